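"""PANTHER-style pathway over-representation analysis.

For an analyzed gene list of size A inside a reference universe of size N,
each annotation category with ref_count members yields

    expected = ref_count * A / N
    fold     = obs_count / expected        (0 when obs_count = 0)
    direction = "+" if obs_count >= expected else "-"

with a one-sided Fisher's exact p-value taken in the row's direction (upper
tail for over-, lower tail for under-representation) and a BH FDR across
the category family. Reference genes belonging to no category are reported
as a trailing "Unclassified" pseudo-category, the usual sink row of
annotation-database reports.

``infer_reference_total`` inverts the expected-count formula to recover the
reference universe N from a single printed report row — useful to redo the
arithmetic of a published table whose underlying annotation version is
unavailable. The largest row (typically Unclassified) gives the stable
estimate, since rounding error on a small printed expected value dominates
the reconstruction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .signature_io import AnnotationCollection, GeneId
from .stats import bh_adjust, fisher_overrepresentation

__all__ = [
    "EnrichmentRow",
    "enrich",
    "unclassified_row",
    "infer_reference_total",
    "round2",
    "write_enrichment_table",
]

UNCLASSIFIED = "Unclassified"


def round2(x: float) -> float:
    """Round to two decimals, half away from zero (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentRow:
    """One category's over-representation record (one report line)."""

    category: str
    ref_count: int
    obs_count: int
    expected: float
    direction: str  # "+" or "-"
    fold: float
    p_raw: float
    fdr: float
    genes: tuple[GeneId, ...] = ()


def _make_row(
    category: str,
    ref_count: int,
    obs_count: int,
    analyzed_total: int,
    reference_total: int,
    genes: tuple[GeneId, ...] = (),
) -> EnrichmentRow:
    expected = ref_count * analyzed_total / reference_total
    direction = "+" if obs_count >= expected else "-"
    fold = obs_count / expected if expected > 0 else 0.0
    # hypergeometric tail in the row's direction
    if direction == "+":
        p_raw = fisher_overrepresentation(
            obs_count,
            analyzed_total - obs_count,
            ref_count - obs_count,
            reference_total - analyzed_total - ref_count + obs_count,
        )
    else:
        p_raw = float(
            hypergeom.cdf(obs_count, reference_total, ref_count, analyzed_total)
        )
    return EnrichmentRow(
        category=category,
        ref_count=ref_count,
        obs_count=obs_count,
        expected=expected,
        direction=direction,
        fold=fold,
        p_raw=p_raw,
        fdr=p_raw,
        genes=genes,
    )


def row_from_counts(
    category: str,
    ref_count: int,
    obs_count: int,
    analyzed_total: int,
    reference_total: int,
) -> EnrichmentRow:
    """Redo one report row's arithmetic from printed counts alone."""
    if reference_total < analyzed_total:
        raise ValueError("reference_total smaller than the analyzed list")
    if obs_count > ref_count or obs_count > analyzed_total:
        raise ValueError("observed count exceeds a margin")
    return _make_row(category, ref_count, obs_count, analyzed_total, reference_total)


def enrich(
    analyzed: set[GeneId],
    annotations: AnnotationCollection,
    include_unclassified: bool = True,
) -> list[EnrichmentRow]:
    """Over-representation of ``analyzed`` against every annotation category.

    The analyzed list is assumed to live inside the reference universe
    (A = |analyzed|). Rows are sorted by fold enrichment descending with the
    Unclassified pseudo-row last; FDR is BH across all emitted rows.
    """
    if not analyzed & annotations.annotated_genes() and not include_unclassified:
        raise ValueError("analyzed list shares no gene with the annotations")
    a_total = len(analyzed)
    n_total = annotations.reference_total
    if n_total < a_total:
        raise ValueError(
            f"reference_total ({n_total}) < analyzed-list size ({a_total})"
        )
    rows: list[EnrichmentRow] = []
    for name in sorted(annotations.categories):
        members = annotations.categories[name]
        hits = analyzed & members
        rows.append(
            _make_row(
                name,
                len(members),
                len(hits),
                a_total,
                n_total,
                tuple(sorted(hits)),
            )
        )
    rows.sort(key=lambda r: (-r.fold, r.category))
    if include_unclassified:
        uncl = unclassified_row(analyzed, annotations)
        if uncl is not None:
            rows.append(uncl)
    fdrs = bh_adjust([r.p_raw for r in rows])
    for row, fdr in zip(rows, fdrs):
        row.fdr = fdr
    return rows


def unclassified_row(
    analyzed: set[GeneId], annotations: AnnotationCollection
) -> EnrichmentRow | None:
    """Pseudo-category of reference genes in no pathway; None (suppressed)
    when the whole reference is annotated."""
    annotated = annotations.annotated_genes()
    ref_count = annotations.reference_total - len(annotated)
    if ref_count <= 0:
        return None
    hits = analyzed - annotated
    return _make_row(
        UNCLASSIFIED,
        ref_count,
        len(hits),
        len(analyzed),
        annotations.reference_total,
        tuple(sorted(hits)),
    )


def infer_reference_total(
    row_ref_count: int, row_expected: float, analyzed_size: int
) -> int:
    """Recover the reference-universe size N from expected = ref * A / N."""
    if row_expected <= 0:
        raise ValueError("row_expected must be positive")
    return round(row_ref_count * analyzed_size / row_expected)


def write_enrichment_table(rows: Sequence[EnrichmentRow], stream: IO[str]) -> None:
    """TSV report with the standard columns; expected/fold at two decimals."""
    df = pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "ref_count": [r.ref_count for r in rows],
            "obs_count": [r.obs_count for r in rows],
            "expected": [round2(r.expected) for r in rows],
            "direction": [r.direction for r in rows],
            "fold": [round2(r.fold) for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "fdr": [r.fdr for r in rows],
            "genes": [
                ",".join(g.symbol or str(g.entrez) for g in r.genes) for r in rows
            ],
        }
    )
    df.to_csv(stream, sep="\t", index=False)
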