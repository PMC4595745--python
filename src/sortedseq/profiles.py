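"""Sample and gene structure: correlation-distance MDS, DEG clustering,
marker-based purity QC, and the spliced-isoform fraction test.

Sample similarity uses the pseudo-distance 1 - Pearson correlation of
log2(TPM + 1) over robustly expressed genes (group mean CPM above a
cutoff), embedded by classical (Torgerson) multidimensional scaling.  DEG
are clustered on 1 - gene-gene correlation across samples with average
linkage.  Purity is summarized as fold-depletion of non-neuronal marker
genes against reference profiles.  Isoform splicing is compared between
groups with an unpaired one-tailed pooled-variance t-test on per-sample
spliced fractions, also available from printed summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import CountMatrix, GeneSetCollection, SampleDesign, ValidationError
from .quantify import ExpressionMatrix, group_mean_cpm

__all__ = [
    "MdsEmbedding",
    "ClusterResult",
    "PurityReport",
    "SplicingFraction",
    "correlation_distance",
    "classical_mds",
    "cluster_deg",
    "purity_report",
    "splicing_fraction_test",
    "splicing_test_from_summary",
]


@dataclass
class MdsEmbedding:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # all eigenvalues, descending
    genes_used: list

    def plot(self, design: SampleDesign | None = None, ax=None):
        """Scatter of the first two coordinates, colored by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        xy = self.coordinates.iloc[:, :2]
        if design is not None:
            labels = design.group_labels().reindex(xy.index)
            for g in sorted(labels.unique()):
                sub = xy[labels == g]
                ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=g)
            ax.legend(fontsize=8)
        else:
            ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1])
        ax.set_xlabel("MDS 1")
        ax.set_ylabel("MDS 2")
        return ax


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix over genes
    gene_order: list  # dendrogram leaf order
    correlation: pd.DataFrame  # gene x gene Pearson r across samples
    max_expression: pd.Series  # per-gene max across samples


@dataclass
class PurityReport:
    per_marker: pd.DataFrame  # marker, set, group, sample_mean, reference, fold_depletion
    per_set_min_fold: pd.Series


@dataclass
class SplicingFraction:
    fractions: pd.Series | None  # per-sample spliced/(spliced+unspliced)
    group_means: dict  # group -> (mean, sem, n)
    t: float
    df: float
    p_one_tailed: float


# ---------------------------------------------------------------------------


def correlation_distance(
    tpm: ExpressionMatrix,
    cpm: ExpressionMatrix,
    design: SampleDesign,
    cpm_min: float = 20.0,
    exclude_genes: list | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """1 - Pearson correlation between sample profiles.

    Genes are filtered to those with group mean CPM > ``cpm_min`` in at
    least one group ("robustly expressed"); profiles are log2(TPM + 1) by
    default.  ``exclude_genes`` removes e.g. the cell-type-defining
    transcripts before computing similarity.
    """
    if tpm.values.shape[1] < 3:
        raise ValidationError("need at least 3 samples")
    gmeans = group_mean_cpm(cpm, design)
    keep = gmeans.index[(gmeans > cpm_min).any(axis=1)]
    if exclude_genes:
        keep = keep.difference(pd.Index(exclude_genes))
    mat = tpm.values.loc[keep]
    x = np.log2(mat.to_numpy() + 1.0) if log_transform else mat.to_numpy()
    sds = x.std(axis=0)
    flat = [mat.columns[j] for j in np.flatnonzero(sds == 0)]
    if flat:
        raise ValidationError(f"constant expression profile, correlation undefined: {flat}")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


def classical_mds(dist: pd.DataFrame, k: int = 2) -> MdsEmbedding:
    """Torgerson classical scaling of a symmetric zero-diagonal distance.

    Double-centers the squared distances, eigendecomposes, and scales the
    top-k eigenvectors by the square roots of their (non-negative)
    eigenvalues.  Coordinates are centered at the origin by construction.
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-12).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"only {k_eff} positive eigenvalues; embedding reduced to k={k_eff}")
    if k_eff == 0:
        coords = np.zeros((n, k))
        k_eff = k
    else:
        coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    return MdsEmbedding(
        coordinates=pd.DataFrame(
            coords, index=dist.index, columns=[f"MDS{i+1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=evals,
        genes_used=[],
    )


def cluster_deg(
    expr: ExpressionMatrix,
    deg_genes: list,
    linkage_method: str = "average",
) -> ClusterResult:
    """Cluster DEG on 1 - Pearson correlation across samples.

    Expression is standardized per gene before correlating; zero-variance
    genes are excluded with a warning.
    """
    genes = [g for g in deg_genes if g in expr.values.index]
    if len(genes) < 2:
        raise ValidationError("need at least 2 DEG to cluster")
    mat = expr.values.loc[genes]
    sds = mat.std(axis=1, ddof=0)
    flat = list(mat.index[sds == 0])
    if flat:
        warnings.warn(f"excluding zero-variance genes: {flat[:5]}")
        mat = mat.drop(index=flat)
        if mat.shape[0] < 2:
            raise ValidationError("fewer than 2 genes with variance")
    z = mat.sub(mat.mean(axis=1), axis=0).div(mat.std(axis=1, ddof=0), axis=0)
    r = np.corrcoef(z.to_numpy())
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(link)
    return ClusterResult(
        linkage=link,
        gene_order=[mat.index[i] for i in order],
        correlation=pd.DataFrame(r, index=mat.index, columns=mat.index),
        max_expression=expr.values.loc[mat.index].max(axis=1),
    )


def purity_report(
    expr: ExpressionMatrix,
    marker_sets: GeneSetCollection,
    reference_profiles: pd.DataFrame,
    design: SampleDesign | None = None,
    pseudocount: float = 1.0,
) -> PurityReport:
    """Fold-depletion of contaminating-cell-type markers in the samples.

    ``reference_profiles`` is marker gene x source cell type expression
    (same unit as ``expr``); fold-depletion is
    (reference + pseudocount) / (sample mean + pseudocount).  Markers
    absent from either table are skipped with a warning.
    """
    if design is not None:
        groups = design.groups()
    else:
        groups = {"all": list(expr.values.columns)}
    rows = []
    for set_name, members in marker_sets.items():
        for marker in sorted(members):
            if marker not in expr.values.index or marker not in reference_profiles.index:
                warnings.warn(f"marker {marker!r} absent, skipped")
                continue
            reference = float(reference_profiles.loc[marker].max())
            for group, samples in groups.items():
                sample_mean = float(expr.values.loc[marker, samples].mean())
                fold = (reference + pseudocount) / (sample_mean + pseudocount)
                rows.append(
                    {
                        "marker": marker,
                        "set": set_name,
                        "group": group,
                        "sample_mean": sample_mean,
                        "reference": reference,
                        "fold_depletion": fold,
                    }
                )
    if not rows:
        raise ValidationError("no marker gene found in both expression and reference")
    per_marker = pd.DataFrame(rows)
    per_set = per_marker.groupby("set")["fold_depletion"].min()
    return PurityReport(per_marker=per_marker, per_set_min_fold=per_set)


# ---------------------------------------------------------------------------
# splicing fraction
# ---------------------------------------------------------------------------


def _pooled_t(m1, v1, n1, m2, v2, n2, welch: bool = False):
    """One-tailed two-sample t of group2 > group1; returns (t, df, p)."""
    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (
            (v1 / n1 + v2 / n2) ** 2
            / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            if se > 0
            else n1 + n2 - 2
        )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    eps = 1e-9 * max(1.0, abs(m1), abs(m2))
    if se <= eps:
        # degenerate: (near-)constant groups give a null or saturated result
        t = 0.0 if abs(m2 - m1) <= eps else np.sign(m2 - m1) * np.inf
    else:
        t = (m2 - m1) / se
    p = float(stats.t.sf(t, df))
    return float(t), float(df), p


def splicing_fraction_test(
    spliced: pd.Series,
    unspliced: pd.Series,
    design: SampleDesign,
    group_deprived: str,
    group_fed: str,
    variance: str = "pooled",
) -> SplicingFraction:
    """One-tailed t-test that the spliced fraction rises under deprivation.

    ``spliced``/``unspliced`` are per-sample counts of the two isoforms;
    the per-sample fraction is spliced / (spliced + unspliced).  Samples
    with zero total are excluded with a warning.  Groups are
    '<cell_type>.<condition>' labels; the alternative is
    fraction(deprived) > fraction(fed).
    """
    groups = design.groups()
    for g in (group_deprived, group_fed):
        if g not in groups:
            raise ValidationError(f"unknown group {g!r}")
    total = spliced + unspliced
    zero = list(total.index[total == 0])
    if zero:
        warnings.warn(f"samples with zero isoform total excluded: {zero}")
    frac = (spliced / total).dropna()

    def group_values(g):
        samples = [s for s in groups[g] if s in frac.index]
        if len(samples) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 usable samples")
        return frac[samples]

    fed_vals = group_values(group_fed)
    dep_vals = group_values(group_deprived)
    t, df, p = _pooled_t(
        fed_vals.mean(), fed_vals.var(ddof=1), len(fed_vals),
        dep_vals.mean(), dep_vals.var(ddof=1), len(dep_vals),
        welch=(variance == "welch"),
    )
    return SplicingFraction(
        fractions=frac,
        group_means={
            group_fed: (float(fed_vals.mean()), float(fed_vals.sem()), len(fed_vals)),
            group_deprived: (float(dep_vals.mean()), float(dep_vals.sem()), len(dep_vals)),
        },
        t=t,
        df=df,
        p_one_tailed=p,
    )


def splicing_test_from_summary(
    mean_fed: float,
    sem_fed: float,
    n_fed: int,
    mean_deprived: float,
    sem_deprived: float,
    n_deprived: int,
    variance: str = "pooled",
) -> SplicingFraction:
    """Same one-tailed test from printed summary statistics (mean, sem, n)."""
    v1 = sem_fed ** 2 * n_fed
    v2 = sem_deprived ** 2 * n_deprived
    t, df, p = _pooled_t(
        mean_fed, v1, n_fed, mean_deprived, v2, n_deprived, welch=(variance == "welch")
    )
    return SplicingFraction(
        fractions=None,
        group_means={
            "fed": (mean_fed, sem_fed, n_fed),
            "deprived": (mean_deprived, sem_deprived, n_deprived),
        },
        t=t,
        df=df,
        p_one_tailed=p,
    )
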