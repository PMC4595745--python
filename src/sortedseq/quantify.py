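"""Within-sample expression units (CPM, FPKM, TPM) and the expression filter.

CPM divides counts by the library size in millions.  FPKM additionally
divides by the gene's summed exon length in kilobases.  TPM rescales FPKM so
every sample's values sum to one million, making values comparable across
libraries of different composition.  Library size is the column sum over all
rows — spike-ins included — so that spike-in rows carry TPM values usable
for calibration; ``exclude_spikes`` restricts the TPM denominator to
endogenous genes instead.

The expression filter retains genes with CPM strictly greater than
``min_cpm`` in at least ``min_samples`` samples; the DEG abundance screen
uses per-group arithmetic mean CPM.  Both use raw (non-TMM) library sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleDesign, ValidationError

__all__ = [
    "ExpressionMatrix",
    "compute_cpm",
    "compute_fpkm",
    "fpkm_to_tpm",
    "compute_tpm",
    "filter_expressed",
    "group_mean_cpm",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued expression with a unit tag."""

    values: pd.DataFrame
    unit: str  # one of CPM, FPKM, TPM
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "FPKM", "TPM"):
            raise ValidationError(f"unknown expression unit: {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _library_sizes(counts: CountMatrix) -> pd.Series:
    lib = counts.library_sizes()
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValidationError(f"zero library size for samples: {zero}")
    return lib.astype(float)


def compute_cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: counts / library size x 1e6."""
    lib = _library_sizes(counts)
    values = counts.counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(values, "CPM", {"library_sizes": lib.to_dict()})


def compute_fpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of exon per million library reads."""
    lib = _library_sizes(counts)
    values = counts.counts.div(counts.exon_length_kb, axis=0).div(lib / 1e6, axis=1)
    return ExpressionMatrix(values, "FPKM", {"library_sizes": lib.to_dict()})


def fpkm_to_tpm(fpkm: ExpressionMatrix, exclude_spikes_mask: pd.Series | None = None) -> ExpressionMatrix:
    """Rescale FPKM so each column sums to 1e6.

    When ``exclude_spikes_mask`` is given (boolean per gene, True = spike),
    the column denominator sums non-spike rows only; spike rows are still
    assigned values on the same scale.
    """
    if fpkm.unit != "FPKM":
        raise ValidationError("fpkm_to_tpm expects an FPKM matrix")
    vals = fpkm.values
    if exclude_spikes_mask is not None:
        denom = vals.loc[~exclude_spikes_mask.reindex(vals.index).fillna(False)].sum(axis=0)
    else:
        denom = vals.sum(axis=0)
    zero = denom.index[denom == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero FPKM column for samples: {zero}")
    values = vals.div(denom, axis=1) * 1e6
    prov = dict(fpkm.provenance)
    prov["tpm_excludes_spikes"] = exclude_spikes_mask is not None
    return ExpressionMatrix(values, "TPM", prov)


def compute_tpm(counts: CountMatrix, exclude_spikes: bool = False) -> ExpressionMatrix:
    """FPKM -> TPM in one step from raw counts."""
    mask = counts.is_spike if exclude_spikes else None
    return fpkm_to_tpm(compute_fpkm(counts), mask)


def filter_expressed(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> list[str]:
    """Genes with CPM > ``min_cpm`` (strict) in >= ``min_samples`` samples.

    Order-preserving.  The strict inequality follows the DEG pipeline's
    "CPM larger than 1" phrasing.
    """
    if min_samples > counts.n_samples:
        raise ValidationError(
            f"min_samples={min_samples} exceeds number of samples ({counts.n_samples})"
        )
    cpm = compute_cpm(counts).values
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return list(cpm.index[keep])


def group_mean_cpm(cpm: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Arithmetic mean CPM per gene within each (cell_type, condition) group.

    Returns a gene x group DataFrame with '<cell_type>.<condition>' columns.
    """
    if cpm.unit != "CPM":
        raise ValidationError("group_mean_cpm expects a CPM matrix")
    groups = design.groups()
    out = {}
    for label, samples in groups.items():
        if not samples:
            raise ValidationError(f"empty group {label!r}")
        missing = [s for s in samples if s not in cpm.values.columns]
        if missing:
            raise ValidationError(f"group {label!r} samples absent from matrix: {missing}")
        out[label] = cpm.values[samples].mean(axis=1)
    return pd.DataFrame(out, index=cpm.values.index)
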