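"""Interference statistics: does the disease model share more genes with the
drug mechanism-of-action set than chance predicts?

The overlap of the disease gene set D and drug gene set G inside a background
universe U is laid out as the 2x2 table

    a = |D n G|    b = |D \\ G|
    c = |G \\ D|   d = |U \\ (D u G)|

and tested one-sided (over-representation) with Fisher's exact test: the
upper tail of the hypergeometric distribution of a with margins (a+b, a+c)
in a universe of size N = a+b+c+d. Small universes are summed exactly in
rational arithmetic; large ones use the scipy hypergeometric survival
function. Families of tests are adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .mcode import ProcessSegment
from .signature_io import GeneId, GeneSignature

__all__ = [
    "OverlapResult",
    "SegmentOverlap",
    "SegmentOverlapReport",
    "fisher_overrepresentation",
    "bh_adjust",
    "interfere",
    "segment_overlap_map",
]

_EXACT_N_LIMIT = 300  # exact rational tail summation below this universe size


def fisher_overrepresentation(a: int, b: int, c: int, d: int) -> float:
    """One-sided (upper tail) Fisher's exact p-value for over-representation.

    p = P(X >= a) for X ~ Hypergeom(N = a+b+c+d, K = a+b, n = a+c).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise ValueError(f"count {name} is negative: {v}")
    n_total = a + b + c + d
    if n_total < 1:
        raise ValueError("empty 2x2 table")
    k_margin = a + b
    n_margin = a + c
    if n_total <= _EXACT_N_LIMIT:
        denom = comb(n_total, n_margin)
        tail = sum(
            comb(k_margin, k) * comb(n_total - k_margin, n_margin - k)
            for k in range(a, min(k_margin, n_margin) + 1)
        )
        return float(Fraction(tail, denom))
    return float(hypergeom.sf(a - 1, n_total, k_margin, n_margin))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return list(multipletests(pvalues, method="fdr_bh")[1])


@dataclass
class OverlapResult:
    """Overlap of disease and drug gene sets with its 2x2 Fisher test."""

    overlap: set[GeneId]
    table: tuple[int, int, int, int]  # (a, b, c, d)
    p_raw: float
    p_adjusted: float
    significant: bool
    alpha: float = 0.05


def interfere(
    disease: GeneSignature,
    drug: GeneSignature,
    universe: set[GeneId],
    alpha: float = 0.05,
    two_sided: bool = False,
) -> OverlapResult:
    """Test the disease/drug gene-set overlap for over-representation.

    Genes outside the universe are dropped with a warning — the test is only
    meaningful over a common background. ``p_adjusted`` equals ``p_raw``
    here; multiplicity correction across a family of tests is the caller's
    responsibility (see :func:`bh_adjust`).
    """
    if not universe:
        raise ValueError("empty background universe")
    d_set = disease.genes & universe
    g_set = drug.genes & universe
    n_dropped = len(disease.genes - universe) + len(drug.genes - universe)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} signature gene(s) outside the universe dropped",
            stacklevel=2,
        )
    a = len(d_set & g_set)
    b = len(d_set - g_set)
    c = len(g_set - d_set)
    d = len(universe) - a - b - c
    p_upper = fisher_overrepresentation(a, b, c, d)
    if two_sided:
        # two-sided by doubling the smaller tail, capped at 1
        n_total, k_m, n_m = a + b + c + d, a + b, a + c
        p_lower = float(hypergeom.cdf(a, n_total, k_m, n_m))
        p_raw = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        p_raw = p_upper
    return OverlapResult(
        overlap=d_set & g_set,
        table=(a, b, c, d),
        p_raw=p_raw,
        p_adjusted=p_raw,
        significant=p_raw < alpha,
        alpha=alpha,
    )


@dataclass(frozen=True)
class SegmentOverlap:
    segment_id: int
    shared: frozenset[GeneId]

    @property
    def n_shared(self) -> int:
        return len(self.shared)


@dataclass
class SegmentOverlapReport:
    """Per-segment drug overlap, ordered by shared-gene count descending —
    the order in which signature matching walks the molecular processes."""

    overlaps: list[SegmentOverlap]
    total_shared: int
    max_shared: int

    @property
    def shared_genes(self) -> set[GeneId]:
        out: set[GeneId] = set()
        for seg in self.overlaps:
            out |= seg.shared
        return out


def segment_overlap_map(
    segments: Iterable[ProcessSegment], drug: GeneSignature
) -> SegmentOverlapReport:
    """Intersect each process segment with the drug gene set."""
    overlaps = [
        SegmentOverlap(seg.segment_id, frozenset(seg.members & drug.genes))
        for seg in segments
    ]
    overlaps.sort(key=lambda o: (-o.n_shared, o.segment_id))
    distinct: set[GeneId] = set()
    for o in overlaps:
        distinct |= o.shared
    return SegmentOverlapReport(
        overlaps=overlaps,
        total_shared=len(distinct),
        max_shared=max((o.n_shared for o in overlaps), default=0),
    )
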