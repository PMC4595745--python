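"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a pooled sorted-neuron study: two cell types
(appetite-promoting AGRP and appetite-suppressing POMC neurons) under fed
and 24-h food-deprived (FD) conditions with 5-6 replicate pools of ~100
manually sorted cells each.  Endogenous gene counts are negative binomial
around a log-normal baseline abundance, with a programmed fraction of
differentially expressed genes per contrast whose log2 fold-changes are
drawn from a signed uniform mixture; the DEG fraction is asymmetric between
cell types (energy deficit perturbs the AGRP transcriptome far more than
the POMC one).  Spike-in counts are Poisson with capture rate proportional
to copies x length (kb), so the 50%-detection point has the closed form
x50 = ln 2 / rate.  A designated transcript is emitted as a spliced /
unspliced isoform pair via a per-condition binomial split of its parent
count (emulating Xbp1 splicing, an unfolded-protein-response readout), and
trace non-neuronal marker genes emulate sorting contamination.

Ground truth (true DEG flags and effect sizes, true detection midpoint,
true copies per cell at 1 TPM, true spliced fractions) is returned in a
``SimTruth`` so recovery can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneSetCollection,
    SampleDesign,
    SpikeInReference,
    ValidationError,
)

__all__ = ["SimParams", "SimTruth", "SimDataset", "generate_dataset", "generate_null_dataset"]


DEFAULT_MARKERS = {
    "astrocyte": ["Gfap", "Aqp4", "Slc1a3", "Aldh1l1"],
    "oligodendrocyte": ["Plp1", "Mbp", "Mobp", "Mog"],
    "microglia": ["Cx3cr1", "C1qa", "Csf1r", "Tmem119"],
    "endothelial": ["Cldn5", "Flt1", "Pecam1", "Slco1a4"],
}


@dataclass
class SimParams:
    """Generator parameters; defaults emulate the study design at desk scale.

    ``groups`` mirrors the study's replication (n = 5-6 pools per cell
    type x condition, 21 samples).  Library sizes default to ~1e6 reads
    (depth is a parameter, not the study's ~53M).  Per-gene negative
    binomial dispersions are log-normal with median 0.08 (biological CV
    ~0.28), chosen so roughly 80% of 2-fold changes at comfortable
    abundance are detectable at this replication.  The spike ladder is 92
    species in a 2-fold dilution series, and the default capture rate
    ln(2)/22 per copy x kb places the 50%-detection point at 22 copies x kb.
    """

    n_genes: int = 5000
    groups: tuple = (
        ("AGRP", "fed", 5),
        ("AGRP", "FD", 6),
        ("POMC", "fed", 5),
        ("POMC", "FD", 5),
    )
    library_size_mean: float = 1e6
    library_size_sigma: float = 0.35  # lognormal sd of log libsize; ~2x spread either way, matching sorted-pool libraries
    baseline_log_mean: float = 0.0  # lognormal relative abundance
    baseline_log_sd: float = 1.6
    dispersion_log_median: float = 0.05
    dispersion_log_sd: float = 0.5
    # programmed DEG fraction per contrast; asymmetric between cell types
    deg_fraction: dict = field(
        default_factory=lambda: {
            "AGRP.FD-AGRP.fed": 0.05,
            "POMC.FD-POMC.fed": 0.005,
            "AGRP.fed-POMC.fed": 0.04,
        }
    )
    lfc_lo: float = 1.0
    lfc_hi: float = 3.0
    # spike-in ladder: n_spikes species on n_levels 2-fold dilution levels
    n_spikes: int = 92
    n_levels: int = 23
    top_copies: float = 2.0 ** 19
    spike_length_range: tuple = (0.25, 2.0)
    capture_rate: float = float(np.log(2) / 22.0)  # per copy x kb
    # spliced/unspliced pairs: gene -> {condition: spliced fraction}
    splicing: dict = field(
        default_factory=lambda: {"Xbp1": {"fed": 0.074, "FD": 0.156}}
    )
    splicing_parent_cpm: float = 200.0
    # contamination: fraction of pooled cells that are non-neuronal
    contamination_fraction: float = 0.001
    marker_reference_tpm: float = 1000.0
    markers: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKERS.items()})
    n_cells_median: int = 100
    n_cells_sigma: float = 0.3
    n_cells_range: tuple = (44, 214)
    seed: int = 0

    def __post_init__(self) -> None:
        for c, f in self.deg_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"deg_fraction for {c!r} must be in [0,1]")
            if round(f * self.n_genes) > self.n_genes:
                raise ValidationError("requested more DEG than genes")
        if self.capture_rate <= 0:
            raise ValidationError("capture_rate must be positive")
        if self.n_genes < 10:
            raise ValidationError("n_genes too small")

    def replace(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a generated dataset."""

    gene_table: pd.DataFrame  # index gene; columns true_lfc.<contrast>, is_deg.<contrast>
    contrasts: list[str]
    x50_true: float  # copies x kb at 50% detection
    copies_per_cell_true: float  # copies per cell at 1 TPM, mean over samples
    copies_per_cell_by_sample: pd.Series
    spliced_fraction_true: dict  # gene -> {condition: fraction}
    marker_reference: pd.DataFrame  # marker gene x source cell type, TPM
    seed: int
    parent_counts: pd.DataFrame | None = None  # pre-split isoform parents

    def n_true_deg(self, contrast: str) -> int:
        return int(self.gene_table[f"is_deg.{contrast}"].sum())

    def true_lfc(self, contrast: str) -> pd.Series:
        return self.gene_table[f"true_lfc.{contrast}"]


class SimDataset(NamedTuple):
    counts: CountMatrix
    design: SampleDesign
    spike_ref: SpikeInReference
    gene_sets: GeneSetCollection
    truth: SimTruth


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_dataset(params: SimParams) -> SimDataset:
    """Draw one dataset plus ground truth; identical seed, identical output."""
    p = params
    (rng_ab, rng_disp, rng_eff, rng_lib, rng_counts, rng_spike, rng_splice, rng_sets) = _spawn(p.seed, 8)

    # --- gene universe ----------------------------------------------------
    gene_ids = [f"gene_{i:05d}" for i in range(p.n_genes)]
    marker_genes = [g for genes in p.markers.values() for g in genes]
    splice_parents = list(p.splicing)
    all_parents = gene_ids + marker_genes + splice_parents

    base = rng_ab.lognormal(p.baseline_log_mean, p.baseline_log_sd, size=p.n_genes)
    lengths = rng_ab.lognormal(np.log(1.5), 0.5, size=len(all_parents))  # kb

    total_base = base.sum()
    marker_rel = (
        p.contamination_fraction * p.marker_reference_tpm / 1e6 * total_base
    )
    parent_rel = p.splicing_parent_cpm / 1e6 * total_base
    abundance = np.concatenate(
        [base, np.full(len(marker_genes), marker_rel), np.full(len(splice_parents), parent_rel)]
    )

    phi = rng_disp.lognormal(np.log(p.dispersion_log_median), p.dispersion_log_sd, size=len(all_parents))

    # --- group effects ----------------------------------------------------
    cell_types = sorted({g[0] for g in p.groups})
    conditions = sorted({g[1] for g in p.groups})
    base_cond = "fed" if "fed" in conditions else conditions[0]
    contrasts = list(p.deg_fraction)
    n_all = len(all_parents)
    true_lfc = {c: np.zeros(n_all) for c in contrasts}
    for c in contrasts:
        n_deg = int(round(p.deg_fraction[c] * p.n_genes))
        idx = rng_eff.choice(p.n_genes, size=n_deg, replace=False)
        sign = rng_eff.choice([-1.0, 1.0], size=n_deg)
        mag = rng_eff.uniform(p.lfc_lo, p.lfc_hi, size=n_deg)
        true_lfc[c][idx] = sign * mag

    def group_log2_effect(cell: str, cond: str) -> np.ndarray:
        """log2 offset of group (cell, cond) relative to the first cell
        type's baseline-condition group, induced by the contrast effects."""
        eff = np.zeros(n_all)
        for c in contrasts:
            plus, minus = c.split("-")
            pc, pcon = plus.split(".")
            mc, mcon = minus.split(".")
            # within-cell-type condition contrasts
            if pc == mc == cell and {pcon, mcon} == {cond, base_cond} and cond != base_cond:
                eff += true_lfc[c] if pcon == cond else -true_lfc[c]
            # between-cell-type contrast at baseline condition
            if pcon == mcon == base_cond and pc != mc:
                if cell == mc:
                    eff -= true_lfc[c]
        return eff

    # --- samples ----------------------------------------------------------
    rows = []
    for cell, cond, n_rep in p.groups:
        for r in range(n_rep):
            rows.append((f"{cell}.{cond}.{r + 1}", cell, cond))
    sample_ids = [r[0] for r in rows]
    n_samples = len(rows)
    lib = rng_lib.lognormal(
        np.log(p.library_size_mean) - p.library_size_sigma ** 2 / 2,
        p.library_size_sigma,
        size=n_samples,
    )
    n_cells = np.clip(
        np.round(rng_lib.lognormal(np.log(p.n_cells_median), p.n_cells_sigma, size=n_samples)),
        *p.n_cells_range,
    ).astype(int)
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "cell_type": [r[1] for r in rows],
                "condition": [r[2] for r in rows],
                "n_cells": n_cells,
            }
        )
    )

    # --- endogenous counts ------------------------------------------------
    mu = np.empty((n_all, n_samples))
    for j, (_, cell, cond) in enumerate(rows):
        u = abundance * 2.0 ** group_log2_effect(cell, cond)
        mu[:, j] = lib[j] * u / u.sum()
    r_nb = 1.0 / phi
    nb_p = r_nb[:, None] / (r_nb[:, None] + mu)
    counts_parent = rng_counts.negative_binomial(r_nb[:, None], nb_p)

    # --- spike-ins --------------------------------------------------------
    level_copies = p.top_copies / 2.0 ** np.arange(p.n_levels)
    copies = np.array([level_copies[i % p.n_levels] for i in range(p.n_spikes)])
    spike_len = rng_spike.uniform(*p.spike_length_range, size=p.n_spikes)
    spike_ids = [f"ERCC-{i:04d}" for i in range(p.n_spikes)]
    depth = lib / p.library_size_mean
    spike_mu = p.capture_rate * (copies * spike_len)[:, None] * depth[None, :]
    spike_counts = rng_spike.poisson(spike_mu)
    spike_ref = SpikeInReference(
        pd.DataFrame({"spike_id": spike_ids, "length_kb": spike_len, "copies_per_tube": copies})
    )

    # --- spliced / unspliced split ---------------------------------------
    final_ids: list[str] = []
    final_counts: list[np.ndarray] = []
    final_len: list[float] = []
    parent_index = {g: i for i, g in enumerate(all_parents)}
    for i, g in enumerate(all_parents):
        if g in p.splicing:
            continue
        final_ids.append(g)
        final_counts.append(counts_parent[i])
        final_len.append(lengths[i])
    for g, frac_by_cond in p.splicing.items():
        i = parent_index[g]
        fr = np.array([frac_by_cond.get(cond, 0.0) for _, _, cond in rows])
        spliced = rng_splice.binomial(counts_parent[i], fr)
        unspliced = counts_parent[i] - spliced
        final_ids += [f"{g}-s", f"{g}-u"]
        final_counts += [spliced, unspliced]
        final_len += [lengths[i], lengths[i]]

    all_ids = final_ids + spike_ids
    count_arr = np.vstack(final_counts + [spike_counts])
    length_arr = np.concatenate([final_len, spike_len])
    counts = CountMatrix(
        counts=pd.DataFrame(count_arr, index=all_ids, columns=sample_ids),
        exon_length_kb=pd.Series(length_arr, index=all_ids),
        is_spike=pd.Series([g.startswith("ERCC-") for g in all_ids], index=all_ids),
    )

    # --- gene sets --------------------------------------------------------
    sets: dict[str, set[str]] = {k: set(v) for k, v in p.markers.items()}
    first = contrasts[0] if contrasts else None
    if first is not None and true_lfc[first].any():
        deg_idx = np.flatnonzero(true_lfc[first][: p.n_genes])
        null_idx = np.flatnonzero(true_lfc[first][: p.n_genes] == 0)
        n_hit = min(20, deg_idx.size)
        pick = list(rng_sets.choice(deg_idx, size=n_hit, replace=False)) + list(
            rng_sets.choice(null_idx, size=min(80, null_idx.size), replace=False)
        )
        sets["EBOX_LIKE"] = {gene_ids[i] for i in pick}
    sets["RANDOM"] = {gene_ids[i] for i in rng_sets.choice(p.n_genes, size=min(100, p.n_genes), replace=False)}
    gene_sets = GeneSetCollection(sets)

    # --- truth ------------------------------------------------------------
    expected_counts = np.vstack([mu, spike_mu])
    expected_rate = expected_counts / np.concatenate([lengths, spike_len])[:, None]
    s_per_kb = expected_rate.sum(axis=0)  # sum of count/length over all rows
    kappa = s_per_kb / (p.capture_rate * depth * 1e6)  # copies per unit TPM
    cpc_by_sample = pd.Series(kappa / n_cells, index=sample_ids)

    gt = pd.DataFrame(index=pd.Index(all_parents, name="gene"))
    for c in contrasts:
        gt[f"true_lfc.{c}"] = true_lfc[c]
        gt[f"is_deg.{c}"] = true_lfc[c] != 0.0
    truth = SimTruth(
        gene_table=gt,
        contrasts=contrasts,
        x50_true=float(np.log(2) / p.capture_rate),
        copies_per_cell_true=float(cpc_by_sample.mean()),
        copies_per_cell_by_sample=cpc_by_sample,
        spliced_fraction_true={g: dict(v) for g, v in p.splicing.items()},
        marker_reference=pd.DataFrame(
            {
                src: {g: p.marker_reference_tpm for g in genes}
                for src, genes in p.markers.items()
            }
        ).fillna(0.0),
        seed=p.seed,
        parent_counts=pd.DataFrame(
            {g: counts_parent[parent_index[g]] for g in p.splicing},
            index=sample_ids,
        ).T
        if p.splicing
        else None,
    )
    return SimDataset(counts, design, spike_ref, gene_sets, truth)


def generate_null_dataset(params: SimParams) -> SimDataset:
    """As ``generate_dataset`` with every group effect forced to zero.

    DEG fractions are zeroed and the spliced fraction is made identical
    across conditions, so no gene differs between groups except through
    sampling noise and library depth.
    """
    null_splicing = {
        g: {cond: next(iter(v.values())) for cond in v}
        for g, v in params.splicing.items()
    }
    null = params.replace(
        deg_fraction={c: 0.0 for c in params.deg_fraction},
        splicing=null_splicing,
    )
    return generate_dataset(null)
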