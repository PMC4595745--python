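"""Readers and writers for the pipeline's external artifacts.

Formats are deliberately plain: tab-separated tables with ``#``-prefixed
comment headers (UTF-8), MatrixMarket triplets for sparse counts, and GMT
for gene sets.  Gene identifiers are opaque strings; no symbol/accession
mapping is attempted.  Every stochastic output written by this package
embeds the seed and a configuration hash in a comment line so a run can be
reproduced from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "CountMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "SpikeInReference",
    "RunConfig",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_spikein_reference",
    "write_spikein_reference",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with per-gene exon length.

    Parameters
    ----------
    counts : DataFrame
        Integer reads, genes in rows, samples in columns.
    exon_length_kb : Series
        Summed exon length per gene in kilobases, indexed like ``counts``.
    is_spike : Series
        Boolean flag marking spike-in (ERCC) rows.
    """

    counts: pd.DataFrame
    exon_length_kb: pd.Series
    is_spike: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        counts = counts.astype(np.int64)
        counts.index.name = None
        counts.columns.name = None
        self.counts = counts
        self.exon_length_kb = self.exon_length_kb.reindex(counts.index).astype(float)
        self.exon_length_kb.index.name = None
        if self.exon_length_kb.isna().any():
            missing = self.exon_length_kb.index[self.exon_length_kb.isna()].tolist()
            raise ValidationError(f"missing exon length for genes: {missing[:5]}")
        if (self.exon_length_kb <= 0).any():
            raise ValidationError("exon_length_kb must be positive for every gene")
        self.is_spike = self.is_spike.reindex(counts.index).fillna(False).astype(bool)
        if bool(self.is_spike.all()):
            raise ValidationError("count matrix must contain at least one non-spike gene")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Column sums over all rows, spike-ins included."""
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = pd.Index(gene_ids)
        return CountMatrix(
            counts=self.counts.loc[idx],
            exon_length_kb=self.exon_length_kb.loc[idx],
            is_spike=self.is_spike.loc[idx],
        )

    def spikes_only(self) -> "CountMatrix":
        # bypass the at-least-one-gene invariant: spike view is a working subset
        sub = object.__new__(CountMatrix)
        sub.counts = self.counts.loc[self.is_spike]
        sub.exon_length_kb = self.exon_length_kb.loc[self.is_spike]
        sub.is_spike = self.is_spike.loc[self.is_spike]
        return sub

    def drop_spikes(self) -> "CountMatrix":
        keep = ~self.is_spike
        return CountMatrix(self.counts.loc[keep], self.exon_length_kb.loc[keep], self.is_spike.loc[keep])


@dataclass
class SampleDesign:
    """Per-sample cell type, condition and number of sorted cells.

    One row per count-matrix column.  ``(cell_type, condition)`` pairs define
    the groups over which contrasts are formed.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cell_type", "condition", "n_cells")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing columns: {missing}")
        tab = self.table.copy()
        if tab["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in design")
        tab["n_cells"] = tab["n_cells"].astype(int)
        if (tab["n_cells"] <= 0).any():
            raise ValidationError("n_cells must be positive")
        tab["cell_type"] = tab["cell_type"].astype(str)
        tab["condition"] = tab["condition"].astype(str)
        self.table = tab.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_labels(self) -> pd.Series:
        """'<cell_type>.<condition>' label per sample, indexed by sample_id."""
        lab = self.table["cell_type"] + "." + self.table["condition"]
        return pd.Series(lab.to_numpy(), index=self.table["sample_id"].to_numpy())

    def groups(self) -> dict[str, list[str]]:
        """Mapping group label -> sample ids, in label-sorted order."""
        lab = self.group_labels()
        return {g: list(lab.index[lab == g]) for g in sorted(lab.unique())}

    def validate_against(self, counts: CountMatrix) -> None:
        design_samples = set(self.sample_ids)
        count_samples = set(counts.sample_ids)
        missing = count_samples - design_samples
        if missing:
            raise ValidationError(f"samples in counts but absent from design: {sorted(missing)}")
        extra = design_samples - count_samples
        if extra:
            raise ValidationError(f"samples in design but absent from counts: {sorted(extra)}")
        sizes = self.table.groupby(["cell_type", "condition"]).size()
        if (sizes < 2).any():
            small = sizes[sizes < 2].index.tolist()
            raise ValidationError(f"groups with fewer than 2 samples: {small}")

    def reorder(self, sample_ids: Sequence[str]) -> "SampleDesign":
        tab = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleDesign(tab)

    def with_labels(self, cell_types: Sequence[str], conditions: Sequence[str]) -> "SampleDesign":
        tab = self.table.copy()
        tab["cell_type"] = list(cell_types)
        tab["condition"] = list(conditions)
        return SampleDesign(tab)


@dataclass
class GeneSetCollection:
    """Named sets of gene identifiers with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = {str(m) for m in members}

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class SpikeInReference:
    """ERCC-style ladder truth: molecules per tube and length per spike."""

    table: pd.DataFrame  # columns: spike_id, length_kb, copies_per_tube

    REQUIRED = ("spike_id", "length_kb", "copies_per_tube")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"spike-in reference missing columns: {missing}")
        tab = self.table.copy()
        tab["length_kb"] = tab["length_kb"].astype(float)
        tab["copies_per_tube"] = tab["copies_per_tube"].astype(float)
        if (tab["length_kb"] <= 0).any():
            raise ValidationError("spike length_kb must be positive")
        if (tab["copies_per_tube"] < 0).any():
            raise ValidationError("copies_per_tube must be non-negative")
        if tab["spike_id"].duplicated().any():
            raise ValidationError("duplicate spike_id")
        self.table = tab.reset_index(drop=True)

    @property
    def spike_ids(self) -> list[str]:
        return list(self.table["spike_id"])

    def copies_kb(self) -> pd.Series:
        """Abundance axis used for detection modelling: copies x kb."""
        s = self.table["copies_per_tube"] * self.table["length_kb"]
        return pd.Series(s.to_numpy(), index=self.table["spike_id"].to_numpy())


@dataclass
class RunConfig:
    """Run-level configuration: seed, DEG thresholds, permutation count."""

    seed: int = 0
    q_max: float = 0.05
    lfc_min: float = 1.0
    min_cpm: float = 1.0
    min_samples: int = 3
    cpm_min: float = 20.0
    n_permutations: int = 1000
    tpm_exclude_spikes: bool = False
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("q_max", "lfc_min", "min_cpm", "cpm_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.n_permutations <= 0 or self.min_samples <= 0:
            raise ValidationError("n_permutations and min_samples must be positive")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"# seed={self.seed}", f"# config={self.hash()}"]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

SPIKE_PREFIX = "ERCC-"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV or a MatrixMarket triplet.

    The TSV layout is: ``gene_id`` column first, a ``length_kb`` column, an
    optional ``is_spike`` column (0/1), and one column per sample.  When
    ``is_spike`` is absent, rows whose gene id starts with ``ERCC-`` are
    flagged as spikes.  The MTX layout is ``<stem>.mtx`` plus sidecars
    ``<stem>.genes.tsv`` (gene_id, length_kb[, is_spike]) and
    ``<stem>.samples.tsv`` (one sample id per line); indices are 1-based in
    the file per the MatrixMarket standard.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        tab = _read_tsv(path)
        if "length_kb" not in tab.columns:
            raise FormatError("counts TSV must contain a 'length_kb' column")
        gene_col = tab.columns[0]
        tab = tab.set_index(gene_col)
        length = tab.pop("length_kb")
        if "is_spike" in tab.columns:
            is_spike = tab.pop("is_spike").astype(int).astype(bool)
        else:
            is_spike = pd.Series(
                [g.startswith(SPIKE_PREFIX) for g in tab.index], index=tab.index
            )
        arr = tab.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric count entries")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        counts = tab.astype(np.int64)
        return CountMatrix(counts, length, is_spike)
    if format in ("mtx", "mtx-triplet"):
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        mat = scipy.io.mmread(str(stem) + ".mtx")
        genes = pd.read_csv(str(stem) + ".genes.tsv", sep="\t", comment="#", dtype={0: str})
        samples = [
            line.strip()
            for line in Path(str(stem) + ".samples.tsv").read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        if not np.allclose(dense, np.round(dense)):
            raise ValidationError("counts must be integral")
        gene_ids = genes.iloc[:, 0]
        counts = pd.DataFrame(np.round(dense).astype(np.int64), index=gene_ids, columns=samples)
        length = pd.Series(genes["length_kb"].to_numpy(), index=gene_ids)
        if "is_spike" in genes.columns:
            is_spike = pd.Series(genes["is_spike"].astype(bool).to_numpy(), index=gene_ids)
        else:
            is_spike = pd.Series([g.startswith(SPIKE_PREFIX) for g in gene_ids], index=gene_ids)
        return CountMatrix(counts, length, is_spike)
    raise FormatError(f"unknown counts format: {format!r}")


def write_counts(
    cm: CountMatrix,
    path: str | Path,
    format: str = "tsv",
    config: RunConfig | None = None,
) -> None:
    path = Path(path)
    if format == "tsv":
        out = cm.counts.copy()
        out.insert(0, "length_kb", cm.exon_length_kb)
        out.insert(1, "is_spike", cm.is_spike.astype(int))
        with open(path, "w") as fh:
            if config is not None:
                fh.write("\n".join(config.header_lines()) + "\n")
            out.rename_axis("gene_id").reset_index().to_csv(fh, sep="\t", index=False)
        return
    if format in ("mtx", "mtx-triplet"):
        stem = path.with_suffix("") if path.suffix == ".mtx" else path
        scipy.io.mmwrite(str(stem) + ".mtx", scipy.sparse.csr_matrix(cm.counts.to_numpy()))
        genes = pd.DataFrame(
            {
                "gene_id": cm.gene_ids,
                "length_kb": cm.exon_length_kb.to_numpy(),
                "is_spike": cm.is_spike.astype(int).to_numpy(),
            }
        )
        genes.to_csv(str(stem) + ".genes.tsv", sep="\t", index=False)
        Path(str(stem) + ".samples.tsv").write_text("\n".join(cm.sample_ids) + "\n")
        return
    raise FormatError(f"unknown counts format: {format!r}")


def read_design(path: str | Path, counts: CountMatrix | None = None) -> SampleDesign:
    design = SampleDesign(_read_tsv(path))
    if counts is not None:
        design.validate_against(counts)
    return design


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse GMT: one set per line, ``name<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = set(members)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_spikein_reference(path: str | Path) -> SpikeInReference:
    return SpikeInReference(_read_tsv(path))


def write_spikein_reference(ref: SpikeInReference, path: str | Path) -> None:
    ref.table.to_csv(path, sep="\t", index=False)


RESULT_FLOAT_FORMAT = "%.12g"


def write_results(
    frame: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write a results table (e.g. per-gene DE statistics) as TSV.

    Floats are written with 12 significant digits so q-values round-trip.
    """
    with open(path, "w") as fh:
        if config is not None:
            fh.write("\n".join(config.header_lines()) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=RESULT_FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
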