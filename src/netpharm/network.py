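"""Consolidated protein-interaction network and disease-module extraction.

Interaction sources (BioGRID / IntAct / Reactome style edge lists) are merged
into one undirected simple graph: self-loops dropped, duplicate edges merged,
each surviving edge tagged with every source that contributed it. A disease
or drug gene signature is mapped onto this network and its induced subgraph
extracted; mapped genes with no interaction partner inside the signature
(degree zero in the induced subgraph) are pruned, mirroring the construction
of a molecular pathophysiology model from literature-mined genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx

from .signature_io import GeneId, GeneSignature, ParseError

__all__ = [
    "InteractionNetwork",
    "SubgraphResult",
    "consolidate",
    "map_signature",
    "induced_subgraph",
    "read_edge_list",
    "write_edge_list",
]

Edge = tuple[GeneId, GeneId]


@dataclass
class InteractionNetwork:
    """Undirected simple graph over genes with per-edge source provenance."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[GeneId]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[GeneId]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def edge_sources(self, u: GeneId, v: GeneId) -> set[str]:
        return set(self.graph.edges[u, v].get("sources", set()))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class SubgraphResult:
    """Outcome of mapping a signature and extracting its induced subgraph.

    The three sets partition the input signature: ``members`` interact with
    at least one other signature gene, ``isolated`` mapped into the network
    but had no within-signature interaction, ``unmapped`` were absent from
    the network altogether.
    """

    members: set[GeneId]
    isolated: set[GeneId]
    unmapped: set[GeneId]
    graph: nx.Graph  # induced subgraph over members

    def counts(self) -> dict[str, int]:
        return {
            "members": len(self.members),
            "isolated": len(self.isolated),
            "unmapped": len(self.unmapped),
        }


def consolidate(sources: Sequence[tuple[str, Iterable[Edge]]]) -> InteractionNetwork:
    """Union interaction sources into one undirected simple network.

    Self-loops are dropped (they distort degrees and clustering density);
    an edge present in several sources carries the union of their tags.
    """
    if not sources:
        raise ValueError("no interaction sources given")
    g = nx.Graph()
    for tag, edges in sources:
        for u, v in edges:
            if u == v:
                continue
            if g.has_edge(u, v):
                g.edges[u, v]["sources"].add(tag)
            else:
                g.add_edge(u, v, sources={tag})
    return InteractionNetwork(graph=g)


def map_signature(
    net: InteractionNetwork, sig: GeneSignature
) -> tuple[set[GeneId], set[GeneId]]:
    """Split a signature into network-mapped and unmapped genes."""
    node_set = set(net.graph.nodes)
    mapped = sig.genes & node_set
    return mapped, sig.genes - node_set


def induced_subgraph(net: InteractionNetwork, genes: set[GeneId]) -> SubgraphResult:
    """Extract the induced subgraph over ``genes`` and prune degree-zero nodes.

    Bookkeeping identity: |members| + |isolated| + |unmapped| = |genes|.
    """
    node_set = set(net.graph.nodes)
    mapped = genes & node_set
    unmapped = genes - node_set
    sub = net.graph.subgraph(mapped)
    isolated = {n for n in sub.nodes if sub.degree(n) == 0}
    members = mapped - isolated
    return SubgraphResult(
        members=members,
        isolated=isolated,
        unmapped=unmapped,
        graph=nx.Graph(sub.subgraph(members)),
    )


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(
    stream: Iterable[str],
    id_columns: tuple[int, int] = (0, 1),
    source_column: int | None = 2,
    default_tag: str = "edges",
) -> list[tuple[str, Edge]]:
    """Read a tab-delimited edge list into (tag, edge) pairs.

    ``id_columns``/``source_column`` form a minimal column map so that
    BioGRID TAB3 or MITAB exports reduced to Entrez columns can be read by
    pointing at the right columns; a missing source column falls back to
    ``default_tag``.
    """
    i, j = id_columns
    out: list[tuple[str, Edge]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) <= max(i, j):
            raise ParseError(f"expected >= {max(i, j) + 1} columns", lineno)
        try:
            u = GeneId(int(fields[i]))
            v = GeneId(int(fields[j]))
        except ValueError:
            raise ParseError(f"non-integer gene identifier on edge line", lineno) from None
        tag = default_tag
        if source_column is not None and len(fields) > source_column:
            tok = fields[source_column].strip()
            if tok:
                tag = tok
        out.append((tag, (u, v)))
    return out


def edges_by_source(pairs: Iterable[tuple[str, Edge]]) -> list[tuple[str, list[Edge]]]:
    """Group (tag, edge) pairs into the per-source lists `consolidate` takes."""
    grouped: dict[str, list[Edge]] = {}
    for tag, edge in pairs:
        grouped.setdefault(tag, []).append(edge)
    return sorted(grouped.items())


def write_edge_list(net: InteractionNetwork, stream: IO[str]) -> None:
    for u, v in sorted(net.graph.edges, key=lambda e: (min(e).entrez, max(e).entrez)):
        a, b = (u, v) if u < v else (v, u)
        tags = ",".join(sorted(net.graph.edges[u, v].get("sources", set())))
        stream.write(f"{a.entrez}\t{b.entrez}\t{tags}\n")
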