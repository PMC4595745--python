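"""Trimmed mean of M-values (TMM) normalization.

TMM corrects for RNA composition bias between libraries.  For each sample
against a reference sample, gene-wise log2 expression ratios (M) and average
log2 abundances (A) are computed on depth-normalized proportions; genes in
the tails of either the M or the A distribution are trimmed (30% and 5% per
tail by default), and the scaling factor is two to the precision-weighted
mean of the surviving M values, the weights being inverse asymptotic
binomial variances.  Factors are rescaled so their product is one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, ValidationError

__all__ = ["NormalizationFactors", "tmm_factors"]


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (dimensionless, product = 1)."""

    factors: pd.Series
    reference_sample: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValidationError("normalization factors must be positive")


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2^.)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a = m[fin], a[fin]
    obs_f, ref_f = obs[fin], ref[fin]
    n = m.size
    if n == 0:
        warnings.warn("no overlapping expressed genes with reference; factor set to 1")
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    # double trim by rank of M and A, trim_m / trim_a from EACH tail
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        warnings.warn("trimming removed all genes; factor set to 1")
        return 1.0
    # inverse asymptotic binomial variance of M
    w = (n_obs - obs_f) / (n_obs * obs_f) + (n_ref - ref_f) / (n_ref * ref_f)
    mean_m = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(mean_m):
        return 1.0
    return float(2.0 ** mean_m)


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference_sample: str | None = None,
) -> NormalizationFactors:
    """Compute TMM factors for every sample of a (filtered) count matrix.

    The reference is the sample whose upper-quartile count proportion is
    closest to the mean upper-quartile across samples, unless one is named
    explicitly.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if mat.shape[1] < 2:
        raise ValidationError("TMM requires at least two samples")
    arr = mat.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        zero = mat.columns[lib == 0].tolist()
        raise ValidationError(f"zero library size for samples: {zero}")
    f75 = np.quantile(arr / lib, 0.75, axis=0)
    if reference_sample is None:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(mat.columns).index(reference_sample)
    ref = arr[:, ref_idx]
    n_ref = lib[ref_idx]
    raw = np.array(
        [
            1.0
            if j == ref_idx
            else _pair_factor(arr[:, j], ref, lib[j], n_ref, trim_m, trim_a)
            for j in range(arr.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(
        pd.Series(factors, index=mat.columns), str(mat.columns[ref_idx])
    )
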