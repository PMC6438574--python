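import io

import networkx as nx
import pytest

from netpharm.signature_io import GeneId, GeneSignature


def gid(i: int, symbol: str | None = None) -> GeneId:
    return GeneId(i, symbol)


def gset(*ids: int) -> set[GeneId]:
    return {GeneId(i) for i in ids}


def sig(label: str, *ids: int) -> GeneSignature:
    return GeneSignature(label=label, genes=gset(*ids))


def graph_from_edges(*edges: tuple[int, int]) -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from((gid(a), gid(b)) for a, b in edges)
    return g


@pytest.fixture
def text_stream():
    def make(content: str) -> io.StringIO:
        return io.StringIO(content)

    return make
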