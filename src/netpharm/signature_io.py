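"""Readers and writers for the tab-delimited formats the pipeline consumes.

Gene identity is canonically the NCBI Entrez integer ID (the keying used by
``gene2pubmed``); gene symbols are carried along for display only and never
participate in equality, hashing or matching.

Formats handled here:

* ``gene2pubmed``-style associations: 3-column TSV ``tax_id  GeneID  PubMed_ID``
  (``#``-prefixed comment/header lines tolerated).
* Plain gene lists: one Entrez ID per line, optional second column symbol.
* GMT pathway annotations (Broad/MSigDB dialect): ``name  description  gene...``.
* Regulation tables: 4-column TSV ``gene  context  direction  sources``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

__all__ = [
    "GeneId",
    "GeneSignature",
    "RegulationRecord",
    "AnnotationCollection",
    "Context",
    "Direction",
    "ParseError",
    "parse_gene2pubmed",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_regulation_table",
    "write_regulation_table",
]


class ParseError(ValueError):
    """A malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, eq=False, order=False)
class GeneId:
    """A protein-coding gene, identified by its positive Entrez GeneID.

    Equality, hashing and ordering consider the Entrez ID only; ``symbol``
    is a display annotation.
    """

    entrez: int
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.entrez <= 0:
            raise ValueError(f"Entrez GeneID must be positive, got {self.entrez}")

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneId):
            return self.entrez == other.entrez
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.entrez)

    def __lt__(self, other: "GeneId") -> bool:
        return self.entrez < other.entrez

    def __repr__(self) -> str:
        if self.symbol:
            return f"GeneId({self.entrez}, {self.symbol!r})"
        return f"GeneId({self.entrez})"

    def __str__(self) -> str:
        return str(self.entrez)


@dataclass
class GeneSignature:
    """A named gene set with optional per-gene literature provenance.

    ``provenance`` maps a member gene to the PubMed IDs supporting its
    inclusion; genes without literature backing simply have no entry.
    """

    label: str
    genes: set[GeneId] = field(default_factory=set)
    provenance: dict[GeneId, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stray = set(self.provenance) - self.genes
        if stray:
            raise ValueError(
                f"provenance references genes outside the signature: {sorted(stray)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: GeneId) -> bool:
        return gene in self.genes


class Context(str, Enum):
    """Which arm of the comparison a regulation report belongs to."""

    DISEASE = "disease"
    DRUG = "drug"


class Direction(str, Enum):
    """Reported direction of regulation; MIXED marks conflicting reports."""

    UP = "up"
    DOWN = "down"
    MIXED = "mixed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class RegulationRecord:
    gene: GeneId
    context: Context
    direction: Direction
    sources: frozenset[int] = frozenset()


@dataclass
class AnnotationCollection:
    """Pathway annotations: category name -> member genes, plus the size of
    the reference universe the expected-count arithmetic is computed against.

    ``reference_total`` defaults to the size of the union of all categories;
    real annotation databases have a larger universe (genes in no pathway),
    so callers may override it.
    """

    categories: dict[str, set[GeneId]]
    reference_total: int | None = None

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            if not members:
                raise ValueError(f"category {name!r} is empty")
        union = self.annotated_genes()
        if self.reference_total is None:
            self.reference_total = len(union)
        elif self.reference_total < len(union):
            raise ValueError(
                f"reference_total {self.reference_total} smaller than the "
                f"annotation union ({len(union)} genes)"
            )

    def annotated_genes(self) -> set[GeneId]:
        out: set[GeneId] = set()
        for members in self.categories.values():
            out |= members
        return out


# ---------------------------------------------------------------------------
# gene2pubmed
# ---------------------------------------------------------------------------

def parse_gene2pubmed(
    stream: Iterable[str],
    pmid_filter: Iterable[int],
    tax_filter: int = 9606,
    label: str = "signature",
) -> GeneSignature:
    """Extract a gene signature from gene2pubmed-style associations.

    Keeps a gene iff at least one line carries both the requested taxon and a
    PubMed ID from ``pmid_filter``; provenance records every passing PMID per
    gene. Duplicate lines collapse by set semantics, so the result is
    invariant under permutation of the input.
    """
    pmids = {int(p) for p in pmid_filter}
    if not pmids:
        raise ValueError("pmid_filter is empty: the filter would match nothing")

    genes: set[GeneId] = set()
    provenance: dict[GeneId, set[int]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"expected >=3 tab-separated fields, got {len(fields)}", lineno
            )
        try:
            tax_id, gene_id, pmid = (int(fields[0]), int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise ParseError(f"non-integer field ({exc})", lineno) from None
        if tax_id != tax_filter or pmid not in pmids:
            continue
        gene = GeneId(gene_id)
        genes.add(gene)
        provenance.setdefault(gene, set()).add(pmid)
    return GeneSignature(label=label, genes=genes, provenance=provenance)


# ---------------------------------------------------------------------------
# plain gene lists
# ---------------------------------------------------------------------------

def read_gene_list(stream: Iterable[str], label: str = "signature") -> GeneSignature:
    """Read a 1-2 column gene list (Entrez ID, optional symbol).

    Duplicate IDs are deduplicated; a warning reports how many were dropped.
    """
    genes: set[GeneId] = set()
    n_dupes = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        try:
            entrez = int(fields[0])
        except ValueError:
            raise ParseError(f"non-integer gene identifier {fields[0]!r}", lineno) from None
        symbol = fields[1].strip() or None if len(fields) > 1 else None
        gene = GeneId(entrez, symbol)
        if gene in genes:
            n_dupes += 1
        else:
            genes.add(gene)
    if n_dupes:
        warnings.warn(f"{n_dupes} duplicate gene identifier(s) dropped", stacklevel=2)
    if not genes:
        warnings.warn("gene list is empty", stacklevel=2)
    return GeneSignature(label=label, genes=genes)


def write_gene_list(sig: GeneSignature, stream: IO[str]) -> None:
    for gene in sorted(sig.genes):
        if gene.symbol:
            stream.write(f"{gene.entrez}\t{gene.symbol}\n")
        else:
            stream.write(f"{gene.entrez}\n")


# ---------------------------------------------------------------------------
# GMT pathway annotations
# ---------------------------------------------------------------------------

def read_gmt(
    stream: Iterable[str], reference_total: int | None = None
) -> AnnotationCollection:
    """Read a GMT file (``name<TAB>description<TAB>gene...``) into an
    AnnotationCollection. Lines with no gene tokens are skipped with a
    warning; duplicate category names are an error.
    """
    categories: dict[str, set[GeneId]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
            warnings.warn(f"GMT line {lineno} has no genes; skipped", stacklevel=2)
            continue
        name = fields[0]
        if name in categories:
            raise ParseError(f"duplicate category name {name!r}", lineno)
        members: set[GeneId] = set()
        for tok in fields[2:]:
            tok = tok.strip()
            if not tok:
                continue
            try:
                members.add(GeneId(int(tok)))
            except ValueError:
                raise ParseError(f"non-integer gene token {tok!r}", lineno) from None
        categories[name] = members
    return AnnotationCollection(categories=categories, reference_total=reference_total)


def write_gmt(collection: AnnotationCollection, stream: IO[str]) -> None:
    for name in sorted(collection.categories):
        members = "\t".join(str(g.entrez) for g in sorted(collection.categories[name]))
        stream.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# regulation tables
# ---------------------------------------------------------------------------

_DIRECTION_TOKENS = {d.value for d in Direction}


def read_regulation_table(stream: Iterable[str]) -> list[RegulationRecord]:
    """Read a 4-column regulation TSV (gene, context, direction, sources).

    Rows are consolidated to one record per (gene, context); conflicting
    ``up`` and ``down`` reports for the same key become ``mixed`` — the
    explicit marker for literature disagreement that downstream matching
    treats as ambiguous.
    """
    merged: dict[tuple[GeneId, Context], tuple[set[Direction], set[int]]] = {}
    header_seen = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen and fields[0].strip().lower() == "gene":
            header_seen = True
            continue
        if len(fields) < 3:
            raise ParseError("expected columns gene/context/direction[/sources]", lineno)
        try:
            gene = GeneId(int(fields[0]))
        except ValueError:
            raise ParseError(f"non-integer gene {fields[0]!r}", lineno) from None
        ctx_tok = fields[1].strip().lower()
        try:
            context = Context(ctx_tok)
        except ValueError:
            raise ParseError(f"unknown context token {ctx_tok!r}", lineno) from None
        dir_tok = fields[2].strip().lower()
        if dir_tok not in _DIRECTION_TOKENS:
            raise ParseError(f"unknown direction token {dir_tok!r}", lineno)
        direction = Direction(dir_tok)
        sources: set[int] = set()
        if len(fields) > 3 and fields[3].strip():
            for tok in fields[3].split(","):
                tok = tok.strip()
                if tok:
                    sources.add(int(tok))
        key = (gene, context)
        dirs, srcs = merged.setdefault(key, (set(), set()))
        dirs.add(direction)
        srcs |= sources

    records: list[RegulationRecord] = []
    for (gene, context), (dirs, srcs) in merged.items():
        effective = dirs - {Direction.UNKNOWN}
        if not effective:
            direction = Direction.UNKNOWN
        elif effective == {Direction.UP}:
            direction = Direction.UP
        elif effective == {Direction.DOWN}:
            direction = Direction.DOWN
        else:
            direction = Direction.MIXED
        records.append(RegulationRecord(gene, context, direction, frozenset(srcs)))
    records.sort(key=lambda r: (r.gene.entrez, r.context.value))
    return records


def write_regulation_table(records: Iterable[RegulationRecord], stream: IO[str]) -> None:
    stream.write("gene\tcontext\tdirection\tsources\n")
    for rec in sorted(records, key=lambda r: (r.gene.entrez, r.context.value)):
        srcs = ",".join(str(s) for s in sorted(rec.sources))
        stream.write(f"{rec.gene.entrez}\t{rec.context.value}\t{rec.direction.value}\t{srcs}\n")


def regulation_lookup(
    records: Iterable[RegulationRecord],
) -> Mapping[tuple[GeneId, Context], Direction]:
    """Index consolidated records for O(1) direction lookups."""
    return {(r.gene, r.context): r.direction for r in records}
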