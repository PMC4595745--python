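import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sortedseq import (
    DifferentialExpression,
    ValidationError,
    adjust_bh,
    call_deg,
    fit_moderated,
    make_contrasts,
    make_design_matrix,
    tmm_factors,
    voom_transform,
)
from sortedseq.de import VoomFit, squeeze_var
from sortedseq.quantify import filter_expressed
from sortedseq.simulate import SimParams, generate_dataset

from .oracles import wls_t_per_gene


def _toy_voom(y, w, design_matrix):
    genes = [f"g{i}" for i in range(y.shape[0])]
    samples = list(design_matrix.index)
    return VoomFit(
        y=pd.DataFrame(y, index=genes, columns=samples),
        weights=pd.DataFrame(w, index=genes, columns=samples),
        trend_x=np.array([0.0, 1.0]),
        trend_y=np.array([1.0, 1.0]),
        design_matrix=design_matrix,
        effective_lib=pd.Series(1.0, index=samples),
    )


def _two_group_design(n1=3, n2=3):
    from sortedseq import SampleDesign

    tab = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n1 + n2)],
            "cell_type": ["A"] * (n1 + n2),
            "condition": ["fed"] * n1 + ["FD"] * n2,
            "n_cells": [100] * (n1 + n2),
        }
    )
    return SampleDesign(tab)


class TestDesignAndContrasts:
    def test_default_contrasts_mirror_study(self, sim_dataset):
        cmat = make_contrasts(sim_dataset.design)
        assert list(cmat.columns) == [
            "AGRP.FD-AGRP.fed",
            "POMC.FD-POMC.fed",
            "AGRP.fed-POMC.fed",
        ]
        assert (cmat.sum(axis=0) == 0).all()

    def test_design_is_group_indicators(self, sim_dataset):
        x = make_design_matrix(sim_dataset.design)
        assert set(np.unique(x.to_numpy())) == {0.0, 1.0}
        np.testing.assert_allclose(x.sum(axis=1), 1.0)


class TestVoom:
    def test_flat_trend_gives_equal_weights(self):
        # homoscedastic log-scale pseudo-counts: residual sd independent of
        # abundance, so the fitted trend is flat and weights nearly equal
        rng = np.random.default_rng(0)
        n_genes = 500
        mu = rng.uniform(4, 12, size=n_genes)
        y_noise = rng.normal(0.0, 0.4, size=(n_genes, 6))
        counts = pd.DataFrame(
            np.round(2.0 ** (mu[:, None] + y_noise)).astype(int),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(6)],
        )
        design = _two_group_design(3, 3)
        v = voom_transform(counts, make_design_matrix(design))
        w = v.weights.to_numpy()
        assert w.max() / w.min() < 1.1 + 0.15  # lowess wobble on finite data

    def test_trend_decreasing_on_nb_counts(self, sim_dataset):
        cm = sim_dataset.counts
        keep = filter_expressed(cm)
        filtered = cm.subset_genes(keep).drop_spikes()
        v = voom_transform(filtered, make_design_matrix(sim_dataset.design),
                           tmm_factors(filtered))
        lo = np.quantile(v.trend_x, 0.1)
        hi = np.quantile(v.trend_x, 0.9)
        y_lo = np.interp(lo, v.trend_x, v.trend_y)
        y_hi = np.interp(hi, v.trend_x, v.trend_y)
        assert y_lo > y_hi

    def test_weights_positive_finite(self, sim_dataset):
        cm = sim_dataset.counts
        filtered = cm.subset_genes(filter_expressed(cm)).drop_spikes()
        v = voom_transform(filtered, make_design_matrix(sim_dataset.design))
        w = v.weights.to_numpy()
        assert np.isfinite(w).all() and (w > 0).all()

    def test_rank_deficient_design_rejected(self):
        counts = pd.DataFrame(
            np.arange(1, 13).reshape(3, 4),
            index=list("abc"), columns=[f"s{i}" for i in range(4)],
        )
        bad = pd.DataFrame(
            {"g1": [1, 1, 1, 1], "g2": [2, 2, 2, 2]}, index=counts.columns, dtype=float
        )
        with pytest.raises(ValidationError, match="full rank"):
            voom_transform(counts, bad)


class TestModeratedFit:
    def test_d0_zero_matches_ordinary_wls(self):
        rng = np.random.default_rng(4)
        design = _two_group_design(4, 3)
        x = make_design_matrix(design)
        y = rng.normal(size=(30, 7))
        w = rng.uniform(0.5, 2.0, size=(30, 7))
        cmat = make_contrasts(design, ["A.FD-A.fed"])
        table, d0, _, dfres = fit_moderated(_toy_voom(y, w, x), cmat, d0_override=0)
        coef_o, t_o = wls_t_per_gene(y, w, x.to_numpy(), cmat.to_numpy()[:, 0])
        np.testing.assert_allclose(table["log2fc"], coef_o, atol=1e-10)
        np.testing.assert_allclose(table["t"], t_o, atol=1e-10)

    def test_d0_infinite_uses_prior_variance_everywhere(self):
        rng = np.random.default_rng(5)
        design = _two_group_design()
        x = make_design_matrix(design)
        y = rng.normal(size=(25, 6))
        w = np.ones((25, 6))
        cmat = make_contrasts(design, ["A.FD-A.fed"])
        table, d0, s0, _ = fit_moderated(_toy_voom(y, w, x), cmat, d0_override=np.inf)
        # with unit weights and a 2-group design the unscaled se is sqrt(2/3)
        expected_t = table["log2fc"] / (np.sqrt(2.0 / 3.0) * np.sqrt(s0))
        np.testing.assert_allclose(table["t"], expected_t, rtol=1e-10)

    def test_two_group_toy_matches_textbook_pooled_t(self):
        design = _two_group_design(3, 3)
        x = make_design_matrix(design)
        y = np.array([[1.0, 2.0, 3.0, 4.0, 6.0, 5.0]])
        w = np.ones((1, 6))
        cmat = make_contrasts(design, ["A.FD-A.fed"])
        table, *_ = fit_moderated(_toy_voom(y, w, x), cmat, d0_override=0)
        fed, dep = y[0, :3], y[0, 3:]
        assert table["log2fc"][0] == pytest.approx(dep.mean() - fed.mean())
        t_ref, p_ref = stats.ttest_ind(dep, fed, equal_var=True)
        assert table["t"][0] == pytest.approx(t_ref)
        assert table["p"][0] == pytest.approx(p_ref)

    def test_moderated_t_between_limits(self, sim_dataset):
        cm = sim_dataset.counts
        filtered = cm.subset_genes(filter_expressed(cm)).drop_spikes()
        v = voom_transform(filtered, make_design_matrix(sim_dataset.design),
                           tmm_factors(filtered))
        cmat = make_contrasts(sim_dataset.design)
        t_mod = fit_moderated(v, cmat)[0]["t"].abs().to_numpy()
        t_lo = fit_moderated(v, cmat, d0_override=0)[0]["t"].abs().to_numpy()
        t_hi = fit_moderated(v, cmat, d0_override=np.inf)[0]["t"].abs().to_numpy()
        lower = np.minimum(t_lo, t_hi)
        upper = np.maximum(t_lo, t_hi)
        assert ((t_mod >= lower - 1e-9) & (t_mod <= upper + 1e-9)).all()

    def test_saturated_design_rejected(self):
        x = pd.DataFrame({"g1": [1.0, 0.0], "g2": [0.0, 1.0]}, index=["s0", "s1"])
        v = _toy_voom(np.ones((3, 2)), np.ones((3, 2)), x)
        with pytest.raises(ValidationError, match="saturated"):
            fit_moderated(v, pd.DataFrame({"c": [1.0, -1.0]}, index=["g1", "g2"]))


class TestSqueezeVar:
    def test_recovers_prior_on_scaled_chisquare(self):
        # variances drawn from the model: s2 ~ s0^2 * chi2_d / d x (prior F)
        rng = np.random.default_rng(6)
        d0_true, s0_true, df = 8.0, 2.5, 10
        prior = s0_true * d0_true / rng.chisquare(d0_true, size=20000)
        s2 = prior * rng.chisquare(df, size=20000) / df
        d0, s0, _ = squeeze_var(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0 == pytest.approx(s0_true, rel=0.1)


class TestAdjustBh:
    def test_tied_boundary(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.05, 0.05])), [0.05, 0.05])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, ps):
        p = np.array(ps)
        np.testing.assert_allclose(
            adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=31)
        perm = rng.permutation(31)
        np.testing.assert_allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh(np.array([0.5, 1.2]))


class TestCallDeg:
    @pytest.mark.parametrize(
        "q,lfc,cpms,expected",
        [
            (0.04, 1.5, (25.0, 5.0), True),
            (0.04, 0.9, (25.0, 5.0), False),
            (0.04, 2.0, (10.0, 15.0), False),
            (0.06, 2.0, (25.0, 5.0), False),
        ],
    )
    def test_criteria(self, q, lfc, cpms, expected):
        table = pd.DataFrame(
            {"gene": ["g"], "contrast": ["c"], "log2fc": [lfc], "t": [1.0],
             "p": [q], "q": [q]}
        )
        gcpm = pd.DataFrame({"A": [cpms[0]], "B": [cpms[1]]}, index=["g"])
        out = call_deg(table, gcpm)
        assert bool(out["deg_flag"][0]) is expected


class TestAgainstReferenceImplementation:
    def test_matches_limma_voom_on_small_fixture(self, tmp_path):
        """Full chain (TMM, voom weights, moderated t, prior df) vs R limma."""
        data = generate_dataset(SimParams(n_genes=300, seed=42))
        keep = filter_expressed(data.counts)
        cm = data.counts.subset_genes(keep).drop_spikes()
        cm = cm.subset_genes(list(cm.counts.index[cm.counts.sum(axis=1) > 0]))
        cm.counts.to_csv(tmp_path / "counts.tsv", sep="\t")
        data.design.table.to_csv(tmp_path / "design.tsv", sep="\t", index=False)
        script = textwrap.dedent(f"""
            suppressMessages({{library(edgeR); library(limma)}})
            counts <- read.delim("{tmp_path}/counts.tsv", row.names=1, check.names=FALSE)
            tab <- read.delim("{tmp_path}/design.tsv")
            group <- factor(paste(tab$cell_type, tab$condition, sep="."))
            dge <- calcNormFactors(DGEList(counts=as.matrix(counts)), method="TMM")
            X <- model.matrix(~0+group); colnames(X) <- levels(group)
            v <- voom(dge, X)
            fit <- lmFit(v, X)
            cmat <- makeContrasts(c1=AGRP.FD-AGRP.fed, levels=X)
            fit2 <- eBayes(contrasts.fit(fit, cmat))
            out <- data.frame(gene=rownames(counts), lfc=fit2$coefficients[,1],
                              t=fit2$t[,1], p=fit2$p.value[,1])
            write.table(out, "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
            write.table(data.frame(sample=colnames(counts), f=dge$samples$norm.factors),
                        "{tmp_path}/factors.tsv", sep="\\t", row.names=FALSE, quote=FALSE)
        """)
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=600
        )
        assert proc.returncode == 0, proc.stderr
        rfac = pd.read_csv(tmp_path / "factors.tsv", sep="\t").set_index("sample")["f"]
        mine_fac = tmm_factors(cm).factors
        np.testing.assert_allclose(mine_fac, rfac.reindex(mine_fac.index), atol=1e-10)
        v = voom_transform(cm, make_design_matrix(data.design), tmm_factors(cm))
        cmat = make_contrasts(data.design, ["AGRP.FD-AGRP.fed"])
        table, *_ = fit_moderated(v, cmat)
        mine = table.set_index("gene")
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t").set_index("gene")
        np.testing.assert_allclose(mine["log2fc"], ref["lfc"], atol=1e-6)
        np.testing.assert_allclose(mine["t"], ref["t"], atol=1e-5)
        np.testing.assert_allclose(mine["p"], ref["p"], atol=1e-6)


class TestModelObject:
    def test_fit_recovers_programmed_structure(self, sim_dataset):
        res = DifferentialExpression(sim_dataset.counts, sim_dataset.design).fit()
        truth = sim_dataset.truth
        for c in res.contrasts:
            n_true = truth.n_true_deg(c)
            n_called = len(res.deg_genes(c))
            assert n_called == pytest.approx(n_true, abs=max(5, 0.5 * n_true))
        assert "prior df" in res.summary()

    def test_power_within_configured_band(self):
        # sensitivity for programmed 2-fold changes at comfortable abundance
        hits = tot = 0
        for seed in (300, 301, 302):
            d = generate_dataset(SimParams(n_genes=2000, seed=seed, lfc_lo=1.0, lfc_hi=1.0))
            r = DifferentialExpression(d.counts, d.design).fit()
            c = "AGRP.FD-AGRP.fed"
            sub = r.for_contrast(c)
            truth = d.truth.gene_table
            deg = [g for g in truth.index[truth[f"is_deg.{c}"]] if g in sub.index]
            sel = sub.loc[deg, "max_group_cpm"] >= 20
            hits += (sub.loc[deg, "q"][sel] < 0.05).sum()
            tot += int(sel.sum())
        assert 0.6 <= hits / tot <= 0.95
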