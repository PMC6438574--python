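"""Molecular signature matching: does the drug counteract the disease?

For each gene shared by the disease model and the drug mechanism-of-action
set, the literature-reported regulation under disease is compared with that
under drug treatment:

* **discordant** — opposed directions (up with disease, down with drug, or
  vice versa): the drug is predicted to reverse the disease-specific
  expression of that gene;
* **concordant** — same direction: the drug pushes with the disease;
* **ambiguous** — conflicting literature ("mixed") on either side;
* **unknown** — no regulation report on either side.

Matching walks the molecular process segments in decreasing order of shared
gene count — the densest points of drug/disease interference — and rolls the
verdict counts up into a coarse repurposing recommendation whose thresholds
are explicitly analyst-owned configuration, not biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

from .mcode import ProcessSegment
from .signature_io import Context, Direction, GeneId, RegulationRecord, regulation_lookup

__all__ = [
    "Verdict",
    "Recommendation",
    "MatchVerdict",
    "MatchReport",
    "MatchThresholds",
    "classify",
    "match_segment_genes",
    "repurposing_summary",
    "write_match_table",
]


class Verdict(str, Enum):
    DISCORDANT = "discordant"
    CONCORDANT = "concordant"
    AMBIGUOUS = "ambiguous"
    UNKNOWN = "unknown"


class Recommendation(str, Enum):
    SUPPORT = "support"
    NEUTRAL = "neutral"
    AGAINST = "against"


def classify(disease_dir: Direction, drug_dir: Direction) -> Verdict:
    """Classify one gene's disease-vs-drug regulation pair.

    Total over the direction enum: unknown dominates, then mixed
    (ambiguous), then the opposed/equal comparison of {up, down}.
    """
    if Direction.UNKNOWN in (disease_dir, drug_dir):
        return Verdict.UNKNOWN
    if Direction.MIXED in (disease_dir, drug_dir):
        return Verdict.AMBIGUOUS
    if disease_dir == drug_dir:
        return Verdict.CONCORDANT
    return Verdict.DISCORDANT


@dataclass(frozen=True)
class MatchVerdict:
    gene: GeneId
    disease_direction: Direction
    drug_direction: Direction
    verdict: Verdict
    in_segment: int | None = None
    override_applied: bool = False


@dataclass
class MatchReport:
    verdicts: list[MatchVerdict]
    n_discordant: int
    n_concordant: int
    n_ambiguous: int
    n_unknown: int

    @classmethod
    def from_verdicts(cls, verdicts: list[MatchVerdict]) -> "MatchReport":
        counts = {v: 0 for v in Verdict}
        for mv in verdicts:
            counts[mv.verdict] += 1
        return cls(
            verdicts=verdicts,
            n_discordant=counts[Verdict.DISCORDANT],
            n_concordant=counts[Verdict.CONCORDANT],
            n_ambiguous=counts[Verdict.AMBIGUOUS],
            n_unknown=counts[Verdict.UNKNOWN],
        )


def match_segment_genes(
    segments: Sequence[ProcessSegment],
    shared: set[GeneId],
    regulations: Iterable[RegulationRecord],
    overrides: Mapping[GeneId, Verdict] | None = None,
) -> MatchReport:
    """Verdicts for shared genes inside process segments.

    Segments are visited by decreasing shared-gene count (ties by segment
    id), genes within a segment by Entrez ID. A missing regulation record
    yields verdict ``unknown``, never an exception. ``overrides`` carries
    expert adjudication: a hard per-gene verdict that replaces the computed
    one and is flagged in the output.
    """
    lookup = regulation_lookup(regulations)
    overrides = overrides or {}
    ranked = sorted(
        segments, key=lambda s: (-len(s.members & shared), s.segment_id)
    )
    verdicts: list[MatchVerdict] = []
    for seg in ranked:
        for gene in sorted(seg.members & shared):
            disease_dir = lookup.get((gene, Context.DISEASE), Direction.UNKNOWN)
            drug_dir = lookup.get((gene, Context.DRUG), Direction.UNKNOWN)
            verdict = classify(disease_dir, drug_dir)
            applied = False
            if gene in overrides:
                verdict = overrides[gene]
                applied = True
            verdicts.append(
                MatchVerdict(
                    gene=gene,
                    disease_direction=disease_dir,
                    drug_direction=drug_dir,
                    verdict=verdict,
                    in_segment=seg.segment_id,
                    override_applied=applied,
                )
            )
    return MatchReport.from_verdicts(verdicts)


@dataclass(frozen=True)
class MatchThresholds:
    """Analyst-owned decision thresholds for the repurposing call."""

    min_discordant_fraction: float = 0.5  # of resolved verdicts, for "support"


def repurposing_summary(
    report: MatchReport, thresholds: MatchThresholds | None = None
) -> Recommendation:
    """Roll verdict counts into a support/neutral/against recommendation.

    Resolved verdicts are the discordant + concordant ones. Against when
    concordance outweighs discordance; support when the discordant fraction
    of resolved verdicts reaches the configured threshold; neutral otherwise
    or when nothing is resolved (with a warning).
    """
    thresholds = thresholds or MatchThresholds()
    resolved = report.n_discordant + report.n_concordant
    if resolved == 0:
        warnings.warn("no resolved (discordant/concordant) verdicts", stacklevel=2)
        return Recommendation.NEUTRAL
    if report.n_concordant > report.n_discordant:
        return Recommendation.AGAINST
    if report.n_discordant / resolved >= thresholds.min_discordant_fraction:
        return Recommendation.SUPPORT
    return Recommendation.NEUTRAL


def write_match_table(
    report: MatchReport, recommendation: Recommendation, stream: IO[str]
) -> None:
    stream.write("gene\tsegment\tdisease_direction\tdrug_direction\tverdict\toverride_applied\n")
    for mv in report.verdicts:
        seg = mv.in_segment if mv.in_segment is not None else ""
        stream.write(
            f"{mv.gene.entrez}\t{seg}\t{mv.disease_direction.value}\t"
            f"{mv.drug_direction.value}\t{mv.verdict.value}\t{int(mv.override_applied)}\n"
        )
    stream.write(
        f"# discordant={report.n_discordant} concordant={report.n_concordant} "
        f"ambiguous={report.n_ambiguous} unknown={report.n_unknown} "
        f"recommendation={recommendation.value}\n"
    )
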