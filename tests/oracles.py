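"""Independent brute-force re-implementations used as oracles.

Deliberately naive: direct formulas, explicit loops, no code shared with
the package internals.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd


def naive_tmm_factors(counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Direct trimmed weighted mean of M-values, sorting-based trimming."""
    lib = counts.sum(axis=0).astype(float)
    rates = counts.div(lib, axis=1)
    f75 = rates.quantile(0.75, axis=0)
    ref = (f75 - f75.mean()).abs().idxmin()
    out = {}
    for s in counts.columns:
        if s == ref:
            out[s] = 1.0
            continue
        obs, rfc = counts[s].to_numpy(float), counts[ref].to_numpy(float)
        n_o, n_r = lib[s], lib[ref]
        keep = (obs > 0) & (rfc > 0)
        obs, rfc = obs[keep], rfc[keep]
        m = np.log2((obs / n_o) / (rfc / n_r))
        a = 0.5 * np.log2((obs / n_o) * (rfc / n_r))
        n = m.size
        if n == 0 or np.max(np.abs(m)) < 1e-6:
            out[s] = 1.0
            continue
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        rank_m = np.empty(n)
        rank_m[np.argsort(m, kind="stable")] = np.arange(1, n + 1)
        rank_a = np.empty(n)
        rank_a[np.argsort(a, kind="stable")] = np.arange(1, n + 1)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        w = 1.0 / ((n_o - obs) / (n_o * obs) + (n_r - rfc) / (n_r * rfc))
        out[s] = 2.0 ** (np.sum(m[sel] * w[sel]) / np.sum(w[sel]))
    raw = pd.Series(out).reindex(counts.columns)
    return raw / np.exp(np.mean(np.log(raw)))


def wls_t_per_gene(y: np.ndarray, w: np.ndarray, x: np.ndarray, cvec: np.ndarray):
    """Ordinary weighted-least-squares t for one contrast, per gene, by loop."""
    n, p = x.shape
    coefs, ts = [], []
    for g in range(y.shape[0]):
        wg = np.diag(w[g])
        xtwx = x.T @ wg @ x
        beta = np.linalg.solve(xtwx, x.T @ wg @ y[g])
        resid = y[g] - x @ beta
        s2 = float(resid @ wg @ resid) / (n - p)
        var_c = float(cvec @ np.linalg.inv(xtwx) @ cvec)
        coef = float(cvec @ beta)
        coefs.append(coef)
        ts.append(coef / math.sqrt(var_c * s2))
    return np.array(coefs), np.array(ts)


def hypergeom_upper_enumerate(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for i in draw if i < K) >= k:
            hits += 1
    return hits / total


def hypergeom_upper_comb(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct combinatorial sums with exact integers."""
    total = math.comb(N, n)
    hits = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return hits / total


def naive_correlation_distance(mat: np.ndarray) -> np.ndarray:
    """1 - Pearson r between columns, by explicit pairwise loops."""
    n = mat.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi, xj = mat[:, i], mat[:, j]
            r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                math.sqrt(np.sum((xi - xi.mean()) ** 2)) * math.sqrt(np.sum((xj - xj.mean()) ** 2))
            )
            d[i, j] = 1.0 - r
    return d


def grid_search_logistic_x50(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum-likelihood logistic fit by nested grid refinement."""

    def nll(b0, b1):
        z = b0 + b1 * x
        return np.sum(np.logaddexp(0.0, z)) - np.sum(y * z)

    b0s = np.linspace(-20, 20, 81)
    b1s = np.linspace(0.05, 20, 80)
    for _ in range(6):
        vals = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        w0 = b0s[1] - b0s[0]
        w1 = b1s[1] - b1s[0]
        b0s = np.linspace(b0s[i] - 2 * w0, b0s[i] + 2 * w0, 41)
        b1s = np.linspace(max(b1s[j] - 2 * w1, 1e-4), b1s[j] + 2 * w1, 41)
    return 10.0 ** (-b0s[20] / b1s[20])
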