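import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sortedseq import (
    GeneSetCollection,
    ValidationError,
    classical_mds,
    cluster_deg,
    compute_cpm,
    compute_tpm,
    correlation_distance,
    purity_report,
    splicing_fraction_test,
    splicing_test_from_summary,
)
from sortedseq.profiles import _pooled_t
from sortedseq.quantify import ExpressionMatrix
from sortedseq.simulate import DEFAULT_MARKERS, SimParams, generate_dataset

from .oracles import naive_correlation_distance


class TestCorrelationDistance:
    def test_identical_samples_distance_zero(self, sim_dataset):
        tpm = compute_tpm(sim_dataset.counts)
        cpm = compute_cpm(sim_dataset.counts)
        d = correlation_distance(tpm, cpm, sim_dataset.design)
        assert np.allclose(np.diag(d), 0)
        s = sim_dataset.design.sample_ids[0]
        assert d.loc[s, s] == 0.0

    def test_bounds_zero_to_two(self, sim_dataset):
        tpm = compute_tpm(sim_dataset.counts)
        cpm = compute_cpm(sim_dataset.counts)
        d = correlation_distance(tpm, cpm, sim_dataset.design).to_numpy()
        assert (d >= -1e-12).all() and (d <= 2 + 1e-12).all()

    def test_matches_naive_pairwise_loop(self, sim_dataset):
        tpm = compute_tpm(sim_dataset.counts)
        cpm = compute_cpm(sim_dataset.counts)
        from sortedseq.quantify import group_mean_cpm
        gm = group_mean_cpm(cpm, sim_dataset.design)
        keep = gm.index[(gm > 20.0).any(axis=1)]
        mat = np.log2(tpm.values.loc[keep].to_numpy() + 1)
        oracle = naive_correlation_distance(mat)
        mine = correlation_distance(tpm, cpm, sim_dataset.design).to_numpy()
        np.testing.assert_allclose(mine, oracle, atol=1e-12)

    def test_separates_programmed_cell_types(self, sim_dataset):
        tpm = compute_tpm(sim_dataset.counts)
        cpm = compute_cpm(sim_dataset.counts)
        d = correlation_distance(tpm, cpm, sim_dataset.design)
        ct = sim_dataset.design.table.set_index("sample_id")["cell_type"]
        within, between = [], []
        ids = list(d.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                (within if ct[a] == ct[b] else between).append(d.loc[a, b])
        assert stats.mannwhitneyu(between, within, alternative="greater").pvalue < 0.01


class TestClassicalMds:
    def test_reproduces_euclidean_configuration(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = classical_mds(pd.DataFrame(d, index=list("abc"), columns=list("abc")), k=2)
        out = emb.coordinates.to_numpy()
        d_out = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d_out, d, atol=1e-9)
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-9)

    def test_zero_distances_give_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        with pytest.warns(UserWarning):
            emb = classical_mds(d, k=2)
        np.testing.assert_allclose(emb.coordinates.to_numpy(), 0)

    def test_embedding_invariant_to_sample_order(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        names = list("abcdef")
        df = pd.DataFrame(d, index=names, columns=names)
        emb1 = classical_mds(df, k=2)
        perm = list(reversed(names))
        emb2 = classical_mds(df.loc[perm, perm], k=2)
        d1 = np.linalg.norm(
            emb1.coordinates.loc[names].to_numpy()[:, None]
            - emb1.coordinates.loc[names].to_numpy()[None, :], axis=-1)
        d2 = np.linalg.norm(
            emb2.coordinates.loc[names].to_numpy()[:, None]
            - emb2.coordinates.loc[names].to_numpy()[None, :], axis=-1)
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_eigenvalues_sorted_descending(self, sim_dataset):
        tpm = compute_tpm(sim_dataset.counts)
        cpm = compute_cpm(sim_dataset.counts)
        emb = classical_mds(correlation_distance(tpm, cpm, sim_dataset.design))
        ev = emb.eigenvalues
        assert all(ev[i] >= ev[i + 1] - 1e-12 for i in range(len(ev) - 1))


class TestClusterDeg:
    def _expr(self, mat, samples=None):
        samples = samples or [f"s{i}" for i in range(mat.shape[1])]
        return ExpressionMatrix(
            pd.DataFrame(mat, index=[f"g{i}" for i in range(mat.shape[0])],
                         columns=samples), "TPM")

    def test_perfectly_correlated_merge_at_zero(self):
        base = np.array([1.0, 2, 3, 4, 5, 6])
        expr = self._expr(np.vstack([base, 2 * base + 1, -base + 10]))
        res = cluster_deg(expr, ["g0", "g1", "g2"])
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_merges_at_two(self):
        base = np.array([1.0, 2, 3, 4])
        expr = self._expr(np.vstack([base, base[::-1]]))
        res = cluster_deg(expr, ["g0", "g1"])
        assert res.linkage[0, 2] == pytest.approx(2.0)

    def test_block_structure_heights_match_hand_trace(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 5, size=8)
        noiseless = np.vstack([base, base * 3 + 2, 10 - base, 10 - base * 0.5])
        res = cluster_deg(self._expr(noiseless), [f"g{i}" for i in range(4)])
        heights = sorted(res.linkage[:, 2])
        # two exact within-block merges at 0, one cross merge at 1-r = 2
        assert heights[0] == pytest.approx(0.0, abs=1e-12)
        assert heights[1] == pytest.approx(0.0, abs=1e-12)
        assert heights[2] == pytest.approx(2.0)
        assert sorted(res.gene_order) == [f"g{i}" for i in range(4)]

    def test_zero_variance_gene_excluded(self):
        mat = np.vstack([np.arange(5.0), np.ones(5), 2 * np.arange(5.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cluster_deg(self._expr(mat), ["g0", "g1", "g2"])
        assert "g1" not in res.correlation.index


class TestPurityReport:
    def test_direct_arithmetic(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["Gfap"]), "TPM")
        ref = pd.DataFrame({"astrocyte": [1000.0]}, index=["Gfap"])
        rep = purity_report(expr, GeneSetCollection({"astro": {"Gfap"}}), ref)
        assert rep.per_marker.fold_depletion[0] == pytest.approx(1001.0 / 2.0)

    def test_equal_expression_fold_one(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [500.0]}, index=["Mbp"]), "TPM")
        ref = pd.DataFrame({"oligo": [500.0]}, index=["Mbp"])
        rep = purity_report(expr, GeneSetCollection({"o": {"Mbp"}}), ref)
        assert rep.per_marker.fold_depletion[0] == pytest.approx(1.0)

    def test_programmed_contamination_strongly_depleted(self, sim_dataset):
        tpm = compute_tpm(sim_dataset.counts)
        sets = GeneSetCollection({k: set(v) for k, v in DEFAULT_MARKERS.items()})
        rep = purity_report(tpm, sets, sim_dataset.truth.marker_reference,
                            sim_dataset.design)
        assert (rep.per_set_min_fold > 100).all()


class TestSplicingTest:
    def test_identical_fractions_null(self):
        d = generate_dataset(SimParams(n_genes=200, seed=1))
        design = d.design
        samples = design.sample_ids
        spliced = pd.Series(10, index=samples)
        unspliced = pd.Series(90, index=samples)
        res = splicing_fraction_test(spliced, unspliced, design, "AGRP.FD", "AGRP.fed")
        assert res.t == pytest.approx(0.0)
        assert res.p_one_tailed == pytest.approx(0.5)

    def test_three_vs_three_matches_textbook_pooled_t(self):
        fed = np.array([0.05, 0.08, 0.06])
        dep = np.array([0.12, 0.15, 0.18])
        t, df, p = _pooled_t(fed.mean(), fed.var(ddof=1), 3,
                             dep.mean(), dep.var(ddof=1), 3)
        t_ref, p_ref = stats.ttest_ind(dep, fed, equal_var=True)
        assert t == pytest.approx(t_ref)
        assert df == 4
        assert p == pytest.approx(p_ref / 2)  # one-tailed, effect in alternative direction

    def test_recovers_programmed_splicing_shift(self):
        d = generate_dataset(SimParams(n_genes=500, seed=2, splicing_parent_cpm=2000.0))
        s = d.counts.counts.loc["Xbp1-s"]
        u = d.counts.counts.loc["Xbp1-u"]
        res = splicing_fraction_test(s, u, d.design, "AGRP.FD", "AGRP.fed")
        assert res.t > 0

    def test_summary_statistic_interface(self):
        res = splicing_test_from_summary(7.4, 1.0, 5, 15.6, 3.8, 6)
        assert res.df == 9
        assert res.t > 0

    def test_zero_total_sample_excluded(self):
        d = generate_dataset(SimParams(n_genes=200, seed=3))
        samples = d.design.sample_ids
        spliced = pd.Series(5, index=samples)
        unspliced = pd.Series(45, index=samples)
        spliced.iloc[0] = 0
        unspliced.iloc[0] = 0
        with pytest.warns(UserWarning, match="zero isoform total"):
            res = splicing_fraction_test(spliced, unspliced, d.design,
                                         "AGRP.FD", "AGRP.fed")
        assert len(res.fractions) == len(samples) - 1
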