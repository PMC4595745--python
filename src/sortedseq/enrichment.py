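"""Gene-set over-representation among DEG, and DEG-overlap summaries.

Over-representation is the upper-tail hypergeometric probability of the
observed overlap between a gene set and the DEG list, drawn from the
universe of genes that entered the differential-expression fit.  Tests are
one-sided (enrichment); gene sets are intersected with the universe before
counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import DEResults, adjust_bh
from .io import GeneSetCollection, ValidationError

__all__ = ["EnrichmentResult", "hypergeom_upper", "test_set_overrepresentation", "deg_overlap"]


@dataclass
class EnrichmentResult:
    """One gene set's over-representation among one DEG list."""

    set_name: str
    N: int  # universe size
    K: int  # set members in universe
    n: int  # DEG in universe
    k: int  # overlap
    p_upper: float
    frac_up: float  # fraction of overlapping DEG upregulated (NaN if k=0)
    degenerate: bool = False  # set disjoint from universe


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed in log space (no overflow for N of a few tens of thousands).
    Equals 1 when k = 0.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(f"inconsistent hypergeometric counts N={N} K={K} n={n} k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def test_set_overrepresentation(
    deg: DEResults | dict,
    sets: GeneSetCollection,
    universe: list[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in each DEG list.

    ``deg`` is either a fitted :class:`~sortedseq.de.DEResults` (one test
    per contrast) or a mapping of list name -> iterable of DEG gene ids.
    Returns a long DataFrame with N, K, n, k, p and (optionally) a BH q
    across sets within each list.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    N = len(uni_set)
    if isinstance(deg, DEResults):
        lists = {c: set(deg.deg_genes(c)) for c in deg.contrasts}
        lfc = {
            c: deg.for_contrast(c)["log2fc"] for c in deg.contrasts
        }
    else:
        lists = {name: set(genes) for name, genes in deg.items()}
        lfc = {}
    rows = []
    for list_name, deg_genes in lists.items():
        deg_in_uni = deg_genes & uni_set
        n = len(deg_in_uni)
        for set_name, members in sets.items():
            members_in_uni = members & uni_set
            K = len(members_in_uni)
            overlap = members_in_uni & deg_in_uni
            k = len(overlap)
            degenerate = K == 0
            p = 1.0 if degenerate else hypergeom_upper(N, K, n, k)
            if k and list_name in lfc:
                frac_up = float((lfc[list_name].loc[sorted(overlap)] > 0).mean())
            else:
                frac_up = float("nan")
            rows.append(
                EnrichmentResult(set_name, N, K, n, k, p, frac_up, degenerate)
            )
        start = len(rows) - len(sets.sets)
        if adjust:
            ps = np.array([r.p_upper for r in rows[start:]])
            qs = adjust_bh(ps)
            for r, q in zip(rows[start:], qs):
                r.q = float(q)  # type: ignore[attr-defined]
    frame = pd.DataFrame(
        {
            "deg_list": np.repeat(list(lists), len(sets.sets)),
            "set": [r.set_name for r in rows],
            "N": [r.N for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "k": [r.k for r in rows],
            "p": [r.p_upper for r in rows],
            "frac_up": [r.frac_up for r in rows],
            "degenerate": [r.degenerate for r in rows],
        }
    )
    if adjust:
        frame["q"] = [getattr(r, "q", float("nan")) for r in rows]
    return frame


def deg_overlap(deg_lists: dict) -> dict:
    """Exclusive Venn-region counts for up to three DEG lists.

    Keys of the result are '&'-joined list names for each non-empty
    combination (e.g. ``'A'``, ``'A&B'``, ``'A&B&C'``), values are the
    number of genes exclusive to exactly that combination.
    """
    names = list(deg_lists)
    if not 1 <= len(names) <= 3:
        raise ValidationError("deg_overlap supports 1 to 3 lists")
    sets = {name: set(v) for name, v in deg_lists.items()}
    regions: dict[str, int] = {}
    all_genes = set().union(*sets.values())
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(all_genes)
            for name in combo:
                inside &= sets[name]
            for name in names:
                if name not in combo:
                    inside -= sets[name]
            regions["&".join(combo)] = len(inside)
    return regions
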