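"""Moderated differential expression for pooled-cell RNA-seq.

The engine re-implements the precision-weighted moderated-t workflow used
throughout this package:

1. counts are filtered for expression and TMM-normalized;
2. a mean-variance trend is estimated from log2-CPM residual spread and
   inverted into per-observation precision weights (``voom_transform``);
3. per-gene weighted least squares on a group-means design, with residual
   variances shrunk toward a common prior by empirical Bayes
   (``fit_moderated``), gives moderated t-statistics whose null
   distribution is t with augmented degrees of freedom;
4. Benjamini-Hochberg step-up adjustment yields q-values, and the DEG rule
   (q < 0.05, |log2 fc| > 1, group mean CPM > 20 in at least one group)
   flags reported genes.

``DifferentialExpression`` is the model object; ``fit()`` returns a
``DEResults`` carrying estimates, moderated statistics, q-values, per-group
mean CPM, DEG flags and the shrinkage hyperparameters (d0, s0^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix, RunConfig, SampleDesign, ValidationError
from .normalize import NormalizationFactors, tmm_factors
from .quantify import compute_cpm, filter_expressed, group_mean_cpm

__all__ = [
    "make_design_matrix",
    "make_contrasts",
    "VoomFit",
    "voom_transform",
    "fit_moderated",
    "adjust_bh",
    "call_deg",
    "squeeze_var",
    "DifferentialExpression",
    "DEResults",
]


# ---------------------------------------------------------------------------
# design & contrasts
# ---------------------------------------------------------------------------


def make_design_matrix(design: SampleDesign) -> pd.DataFrame:
    """Group-means design: one indicator column per (cell_type, condition).

    No intercept; coefficients are directly interpretable as group means of
    log2-CPM, and contrasts are differences of group means.
    """
    labels = design.group_labels()
    groups = sorted(labels.unique())
    mat = pd.DataFrame(
        {g: (labels == g).astype(float).to_numpy() for g in groups},
        index=labels.index,
    )
    if np.linalg.matrix_rank(mat.to_numpy()) < mat.shape[1]:
        raise ValidationError("design matrix is not full rank")
    return mat


def make_contrasts(
    design: SampleDesign, specs: list[str] | None = None
) -> pd.DataFrame:
    """Contrast matrix (groups x contrasts) from '<g1>-<g2>' strings.

    Default contrasts: within each cell type, deprived-vs-fed; and between
    the two cell types under the first condition (alphabetically, which for
    the fed/FD design is 'FD' < 'fed' reversed — the baseline condition is
    taken as the one named 'fed' when present, else the alphabetically
    first).
    """
    labels = sorted(design.group_labels().unique())
    if specs is None:
        cell_types = sorted({l.split(".")[0] for l in labels})
        conditions = sorted({l.split(".")[1] for l in labels})
        base = "fed" if "fed" in conditions else conditions[0]
        other = [c for c in conditions if c != base]
        specs = []
        for ct in cell_types:
            for cond in other:
                a, b = f"{ct}.{cond}", f"{ct}.{base}"
                if a in labels and b in labels:
                    specs.append(f"{a}-{b}")
        if len(cell_types) >= 2:
            a, b = f"{cell_types[0]}.{base}", f"{cell_types[1]}.{base}"
            if a in labels and b in labels:
                specs.append(f"{a}-{b}")
    cmat = pd.DataFrame(0.0, index=labels, columns=specs)
    for spec in specs:
        plus, minus = spec.split("-")
        if plus not in labels or minus not in labels:
            raise ValidationError(f"contrast {spec!r} references unknown group")
        cmat.loc[plus, spec] = 1.0
        cmat.loc[minus, spec] = -1.0
    return cmat


# ---------------------------------------------------------------------------
# voom: mean-variance trend -> precision weights
# ---------------------------------------------------------------------------


@dataclass
class VoomFit:
    """Log2-CPM, per-observation precision weights and the fitted trend."""

    y: pd.DataFrame  # log2-CPM with 0.5 offset
    weights: pd.DataFrame  # same shape, inverse predicted variance^... sd^-4
    trend_x: np.ndarray  # mean log2 count
    trend_y: np.ndarray  # sqrt residual sd at trend_x
    design_matrix: pd.DataFrame
    effective_lib: pd.Series

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValidationError("voom weights must be positive and finite")


def _ols_batch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene OLS: y is genes x n, shared design x (n x p)."""
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    fitted = beta @ x.T
    resid = y - fitted
    return beta, fitted, resid


def voom_transform(
    counts: CountMatrix | pd.DataFrame,
    design: SampleDesign | pd.DataFrame,
    factors: NormalizationFactors | pd.Series | None = None,
    span: float = 0.5,
) -> VoomFit:
    """Transform counts to log2-CPM with mean-variance precision weights.

    ``y = log2((count + 0.5) / (libsize * factor + 1) * 1e6)``.  Residual
    standard deviations from per-gene OLS fits, fourth-rooted, are smoothed
    against mean log2 count by lowess; each observation's weight is the
    trend-predicted standard deviation at its fitted log2 count raised to
    the power -4 (i.e. inverse predicted variance of log2-CPM), clamped to
    the trend's range at the extremes.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    xmat = design if isinstance(design, pd.DataFrame) else make_design_matrix(design)
    if list(xmat.index) != list(mat.columns):
        xmat = xmat.loc[mat.columns]
    x = xmat.to_numpy()
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValidationError("design matrix is not full rank")
    if n <= p:
        raise ValidationError("no residual degrees of freedom")
    if factors is None:
        fac = pd.Series(1.0, index=mat.columns)
    else:
        fac = factors.factors if isinstance(factors, NormalizationFactors) else factors
        fac = fac.reindex(mat.columns)
    lib = mat.sum(axis=0).astype(float)
    eff = lib * fac
    arr = mat.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        raise ValidationError("genes with zero counts in all samples must be removed before voom")
    y = np.log2((arr + 0.5) / (eff.to_numpy() + 1.0)[None, :] * 1e6)

    beta, fitted, resid = _ols_batch(x, y)
    df_resid = n - p
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(eff.to_numpy() + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    delta = 0.01 * (sx.max() - sx.min())
    lo = lowess(sy, sx, frac=span, it=3, delta=delta, return_sorted=True)
    tx, ty = lo[:, 0], lo[:, 1]
    # collapse duplicate x for interpolation
    ux, first = np.unique(tx, return_index=True)
    uy = ty[first]

    fitted_logcount = fitted + (np.log2(eff.to_numpy() + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, ux, uy)  # clamps at the extremes
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    w = pred_sqrt_sd ** -4

    return VoomFit(
        y=pd.DataFrame(y, index=mat.index, columns=mat.columns),
        weights=pd.DataFrame(w, index=mat.index, columns=mat.columns),
        trend_x=ux,
        trend_y=uy,
        design_matrix=xmat,
        effective_lib=eff,
    )


# ---------------------------------------------------------------------------
# empirical Bayes variance shrinkage
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Moment-matches a scaled-F model on the log variances: with
    z = log(s^2), E z and Var z are known functions of (d0, s0^2) through
    digamma/trigamma, so d0 comes from a trigamma inversion of the excess
    variance of z and s0^2 from the mean.  Returns (d0, s0sq, s2_posterior)
    where the posterior is ``(d0*s0^2 + df*s^2) / (d0 + df)``; when the
    moment equation has no positive root, d0 is infinite and every gene
    gets s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    if n < 2:
        d0, s0sq = np.inf, float(np.exp(emean))
    else:
        evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0, s0sq = np.inf, float(np.exp(emean))
    if np.isinf(d0):
        post = np.full_like(s2, s0sq)
    else:
        post = (d0 * s0sq + df * s2) / (d0 + df)
        post[~ok] = (d0 * s0sq) / (d0 + df)
    return d0, s0sq, post


# ---------------------------------------------------------------------------
# moderated fit
# ---------------------------------------------------------------------------


@dataclass
class DEResults:
    """Per-gene, per-contrast moderated differential expression results.

    Attributes
    ----------
    table : DataFrame
        Long format, one row per (gene, contrast): log2fc, t, p, q,
        per-group mean CPM columns, deg_flag.
    d0, s0_sq : float
        Prior degrees of freedom and prior variance of the shrinkage.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df_residual: float
    contrasts: list[str]
    group_cpm_columns: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def deg_genes(self, contrast: str) -> list[str]:
        sub = self.table[(self.table["contrast"] == contrast) & self.table["deg_flag"]]
        return list(sub["gene"])

    def deg_counts(self) -> dict[str, int]:
        return {c: len(self.deg_genes(c)) for c in self.contrasts}

    def for_contrast(self, contrast: str) -> pd.DataFrame:
        return self.table[self.table["contrast"] == contrast].set_index("gene")

    def summary(self) -> str:
        lines = [
            "Moderated differential expression",
            "=" * 46,
            f"genes tested:        {self.table['gene'].nunique()}",
            f"residual df:         {self.df_residual:.1f}",
            f"prior df (d0):       {self.d0:.3g}",
            f"prior variance s0^2: {self.s0_sq:.4g}",
            "",
            "contrast             DEG   (q<{q}, |lfc|>{l}, CPM>{c})".format(
                q=self.thresholds.get("q_max", 0.05),
                l=self.thresholds.get("lfc_min", 1),
                c=self.thresholds.get("cpm_min", 20),
            ),
        ]
        for c, n in self.deg_counts().items():
            lines.append(f"  {c:<20s}{n:>5d}")
        return "\n".join(lines)


def fit_moderated(
    voom: VoomFit,
    contrasts: pd.DataFrame,
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, float, float, float]:
    """Weighted least squares per gene with moderated t-statistics.

    Returns (long table with gene/contrast/log2fc/t/p columns, d0, s0_sq,
    residual df).  ``d0_override`` of 0 gives ordinary (unmoderated) WLS
    t-statistics; ``numpy.inf`` gives complete shrinkage to the prior.
    """
    x = voom.design_matrix.to_numpy()
    n, p = x.shape
    if n <= p:
        raise ValidationError("saturated design: no residual degrees of freedom")
    y = voom.y.to_numpy()
    w = voom.weights.to_numpy()
    genes = list(voom.y.index)
    cvecs = contrasts.reindex(voom.design_matrix.columns).to_numpy()  # p x k
    if np.isnan(cvecs).any():
        raise ValidationError("contrast references coefficient absent from design")

    # batched WLS: per gene g, beta = (X'W_gX)^-1 X'W_g y_g
    xtwx = np.einsum("ji,gj,jk->gik", x, w, x)  # G x p x p
    xtwy = np.einsum("ji,gj,gj->gi", x, w, y)  # G x p
    cov = np.linalg.inv(xtwx)  # G x p x p
    beta = np.einsum("gik,gk->gi", cov, xtwy)
    fitted = beta @ x.T
    resid = y - fitted
    df_resid = float(n - p)
    s2 = np.einsum("gj,gj->g", w, resid ** 2) / df_resid

    if d0_override is None:
        d0, s0sq, s2_post = squeeze_var(s2, df_resid)
    elif d0_override == 0:
        d0, s0sq, s2_post = 0.0, float("nan"), s2.copy()
    elif np.isinf(d0_override):
        _, s0sq, _ = squeeze_var(s2, df_resid)
        d0, s2_post = float("inf"), np.full_like(s2, s0sq)
    else:
        _, s0sq, _ = squeeze_var(s2, df_resid)
        d0 = float(d0_override)
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)

    coefs = beta @ cvecs  # G x k
    unscaled = np.sqrt(np.einsum("ik,gij,jk->gk", cvecs, cov, cvecs))  # G x k
    df_total = df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        df_total = np.inf
    se = unscaled * np.sqrt(s2_post)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coefs / se
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    frames = []
    for k, cname in enumerate(contrasts.columns):
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "contrast": cname,
                    "log2fc": coefs[:, k],
                    "t": tstat[:, k],
                    "p": pvals[:, k],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return table, float(d0), float(s0sq), df_resid


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("adjust_bh expects a 1-D vector")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_deg(
    table: pd.DataFrame,
    group_cpm: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 1.0,
    cpm_min: float = 20.0,
) -> pd.DataFrame:
    """Flag DEG: q < q_max, |log2fc| > lfc_min, max group mean CPM > cpm_min.

    All three inequalities are strict.  ``group_cpm`` is the gene x group
    mean-CPM frame; its per-gene maximum implements "in at least one cell
    type/condition".
    """
    max_cpm = group_cpm.max(axis=1)
    out = table.copy()
    out["max_group_cpm"] = out["gene"].map(max_cpm)
    out["deg_flag"] = (
        (out["q"] < q_max)
        & (out["log2fc"].abs() > lfc_min)
        & (out["max_group_cpm"] > cpm_min)
    )
    return out


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------


class DifferentialExpression:
    """Moderated DE model over a count matrix and a sample design.

    Parameters
    ----------
    counts : CountMatrix
        Raw integer counts; spike-in rows are used for library size and
        filtering but excluded from the fit.
    design : SampleDesign
        Sample annotations; groups are (cell_type, condition) pairs.
    contrasts : list of '<group>-<group>' strings, optional
        Defaults to deprived-vs-fed within each cell type plus the
        between-cell-type comparison at baseline.
    config : RunConfig, optional
        Thresholds for the expression filter and the DEG call.
    """

    def __init__(
        self,
        counts: CountMatrix,
        design: SampleDesign,
        contrasts: list[str] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        design.validate_against(counts)
        self.counts = counts
        self.design = design.reorder(counts.sample_ids)
        self.config = config or RunConfig()
        self.contrast_matrix = make_contrasts(self.design, contrasts)
        self.design_matrix = make_design_matrix(self.design)

    @classmethod
    def from_frames(
        cls,
        counts: pd.DataFrame,
        lengths_kb: pd.Series,
        design_table: pd.DataFrame,
        **kwargs,
    ) -> "DifferentialExpression":
        is_spike = pd.Series(
            [str(g).startswith("ERCC-") for g in counts.index], index=counts.index
        )
        cm = CountMatrix(counts, lengths_kb, is_spike)
        return cls(cm, SampleDesign(design_table), **kwargs)

    def fit(self, d0_override: float | None = None) -> DEResults:
        cfg = self.config
        keep = filter_expressed(self.counts, cfg.min_cpm, cfg.min_samples)
        filtered = self.counts.subset_genes(keep).drop_spikes()
        nonzero = filtered.counts.sum(axis=1) > 0
        filtered = filtered.subset_genes(list(filtered.counts.index[nonzero]))

        factors = getattr(self, "_fixed_factors", None)
        if factors is None:
            factors = tmm_factors(filtered)
        voom = voom_transform(filtered, self.design_matrix, factors)
        table, d0, s0sq, df_resid = fit_moderated(voom, self.contrast_matrix, d0_override)

        q = np.empty(len(table))
        for cname in self.contrast_matrix.columns:
            mask = (table["contrast"] == cname).to_numpy()
            q[mask] = adjust_bh(table.loc[mask, "p"].to_numpy())
        table["q"] = q

        cpm = compute_cpm(self.counts)
        gcpm = group_mean_cpm(cpm, self.design).loc[filtered.counts.index]
        for col in gcpm.columns:
            table[f"mean_cpm.{col}"] = table["gene"].map(gcpm[col])
        table = call_deg(table, gcpm, cfg.q_max, cfg.lfc_min, cfg.cpm_min)

        res = DEResults(
            table=table,
            d0=d0,
            s0_sq=s0sq,
            df_residual=df_resid,
            contrasts=list(self.contrast_matrix.columns),
            group_cpm_columns=[f"mean_cpm.{c}" for c in gcpm.columns],
            thresholds={"q_max": cfg.q_max, "lfc_min": cfg.lfc_min, "cpm_min": cfg.cpm_min},
        )
        res._voom = voom  # diagnostics: trend & weights
        res._factors = factors
        return res
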