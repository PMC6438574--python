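"""Synthetic inputs with the statistical structure the pipeline assumes.

Every pipeline stage is exercisable without downloads: an Erdős–Rényi
background interaction network with planted dense modules (the "molecular
processes" MCODE should recover), disease/drug gene signatures with a
controlled planted overlap against a fixed universe, pathway annotations of
stated sizes, and per-gene regulation labels with a controlled discordant
fraction.

Default parameters mirror the scale of the motivating study: a reference
universe of 20107 protein-coding genes, a 225-gene disease signature, a
planted disease/drug overlap of 43 genes, and eight planted modules sized
3–16 totalling 64 genes. The drug mechanism-of-action set size (300) is a
typical literature-mined signature size; it is not pinned by any published
count.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical outputs. An optional preferential-attachment background is
available because real protein-interaction degree distributions are
heavy-tailed; the Erdős–Rényi default keeps the null analytically
transparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .network import InteractionNetwork
from .signature_io import (
    Context,
    Direction,
    GeneId,
    GeneSignature,
    AnnotationCollection,
    RegulationRecord,
)

__all__ = [
    "SynthConfig",
    "make_network",
    "make_signatures",
    "make_regulation",
    "make_annotations",
    "write_dataset",
]

# Planted module sizes: 8 modules, 3..16 genes, 64 total.
_DEFAULT_MODULES = (16, 12, 10, 8, 6, 5, 4, 3)
# Pathway category sizes matching a published annotation-table profile.
_DEFAULT_CATEGORIES = (18, 34, 89, 120, 174, 237, 255)


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; the no-argument constructor is the
    study-scale default described in the module docstring."""

    n_genes: int = 20107
    background_degree: float = 4.0
    module_sizes: tuple[int, ...] = _DEFAULT_MODULES
    module_density: float = 0.9
    disease_size: int = 225
    drug_size: int = 300
    overlap_size: int = 43
    discordant_fraction: float = 0.2
    category_sizes: tuple[int, ...] = _DEFAULT_CATEGORIES
    scale_free: bool = False
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("planted modules need >= 2 genes")
        if not 0.0 <= self.module_density <= 1.0:
            raise ValueError("module_density must be in [0, 1]")
        if not 0.0 <= self.discordant_fraction <= 1.0:
            raise ValueError("discordant_fraction must be in [0, 1]")
        if self.overlap_size > min(self.disease_size, self.drug_size):
            raise ValueError("overlap_size exceeds a signature size")
        if max(self.disease_size, self.drug_size) > self.n_genes:
            raise ValueError("signature sizes exceed the gene universe")
        if any(s > self.n_genes for s in self.category_sizes):
            raise ValueError("a category is larger than the gene universe")
        if self.background_degree < 0:
            raise ValueError("background_degree must be >= 0")


def _rng(cfg: SynthConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, salt))


def universe(cfg: SynthConfig) -> list[GeneId]:
    """The gene universe: Entrez-style IDs 1..n_genes."""
    return [GeneId(i) for i in range(1, cfg.n_genes + 1)]


def make_network(cfg: SynthConfig) -> tuple[InteractionNetwork, list[set[GeneId]]]:
    """Background graph with planted dense modules; returns the network and
    the planted ground-truth module memberships.

    Modules occupy disjoint blocks at the start of the ID range; within a
    block each pair is wired with probability ``module_density``, on top of
    an Erdős–Rényi (or Barabási–Albert when ``scale_free``) background at
    mean degree ``background_degree``.
    """
    genes = universe(cfg)
    n = cfg.n_genes
    rng = _rng(cfg, salt=1)
    g = nx.Graph()
    g.add_nodes_from(genes)

    nx_seed = int(rng.integers(2**31 - 1))
    if cfg.background_degree > 0:
        if cfg.scale_free:
            m = max(1, round(cfg.background_degree / 2))
            bg = nx.barabasi_albert_graph(n, m, seed=nx_seed)
        else:
            p = min(1.0, cfg.background_degree / (n - 1))
            bg = nx.fast_gnp_random_graph(n, p, seed=nx_seed)
        for u, v in bg.edges:
            g.add_edge(genes[u], genes[v], sources={"background"})

    truth: list[set[GeneId]] = []
    offset = 0
    for size in cfg.module_sizes:
        block = genes[offset : offset + size]
        offset += size
        for i in range(size):
            for j in range(i + 1, size):
                if cfg.module_density >= 1.0 or rng.random() < cfg.module_density:
                    if g.has_edge(block[i], block[j]):
                        g.edges[block[i], block[j]]["sources"].add("module")
                    else:
                        g.add_edge(block[i], block[j], sources={"module"})
        truth.append(set(block))
    return InteractionNetwork(graph=g), truth


def make_signatures(
    cfg: SynthConfig,
    network: InteractionNetwork,
    module_truth: Sequence[set[GeneId]] | None = None,
) -> tuple[GeneSignature, GeneSignature]:
    """Disease and drug gene signatures over the network's node universe.

    The disease signature preferentially samples planted-module members
    (weight 3:1 against background genes) so that topological segmentation
    captures disease genes, mimicking a literature signature concentrated
    in coherent processes.

    ``overlap_size > 0`` plants exactly that many shared genes (the rest of
    the drug signature avoids the disease set). ``overlap_size = 0`` means
    *no planted association*: the drug signature is drawn independently of
    the disease signature, so any overlap is chance alone — the null the
    interference test is calibrated against.
    """
    nodes = sorted(network.graph.nodes)
    if max(cfg.disease_size, cfg.drug_size) > len(nodes):
        raise ValueError("signature sizes exceed the network node set")
    rng = _rng(cfg, salt=2)

    module_members: set[GeneId] = set()
    for block in module_truth or []:
        module_members |= block
    weights = np.array([3.0 if g in module_members else 1.0 for g in nodes])
    weights /= weights.sum()
    disease_idx = rng.choice(len(nodes), size=cfg.disease_size, replace=False, p=weights)
    disease_genes = {nodes[i] for i in disease_idx}

    if cfg.overlap_size > 0:
        planted = rng.choice(
            sorted(disease_genes), size=cfg.overlap_size, replace=False
        )
        rest_pool = sorted(set(nodes) - disease_genes)
        rest = rng.choice(
            len(rest_pool), size=cfg.drug_size - cfg.overlap_size, replace=False
        )
        drug_genes = set(planted) | {rest_pool[i] for i in rest}
    else:
        drug_idx = rng.choice(len(nodes), size=cfg.drug_size, replace=False)
        drug_genes = {nodes[i] for i in drug_idx}

    return (
        GeneSignature(label="disease", genes=disease_genes),
        GeneSignature(label="drug", genes=drug_genes),
    )


def make_regulation(
    cfg: SynthConfig, overlap_genes: set[GeneId]
) -> list[RegulationRecord]:
    """Up/down regulation labels for the shared genes.

    Exactly ``round(discordant_fraction * |overlap|)`` genes get opposed
    disease/drug directions; the rest are concordant. Disease directions
    are random coin flips.
    """
    genes = sorted(overlap_genes)
    rng = _rng(cfg, salt=3)
    n_disc = round(cfg.discordant_fraction * len(genes))
    disc_idx = set(rng.choice(len(genes), size=n_disc, replace=False)) if genes else set()
    records: list[RegulationRecord] = []
    for i, gene in enumerate(genes):
        disease_dir = Direction.UP if rng.random() < 0.5 else Direction.DOWN
        if i in disc_idx:
            drug_dir = Direction.DOWN if disease_dir is Direction.UP else Direction.UP
        else:
            drug_dir = disease_dir
        records.append(RegulationRecord(gene, Context.DISEASE, disease_dir))
        records.append(RegulationRecord(gene, Context.DRUG, drug_dir))
    return records


def make_annotations(
    cfg: SynthConfig, genes: Sequence[GeneId] | None = None
) -> AnnotationCollection:
    """Pathway categories of the configured sizes, sampled without
    replacement per category (categories may overlap each other);
    reference_total is the full gene universe."""
    pool = list(genes) if genes is not None else universe(cfg)
    rng = _rng(cfg, salt=4)
    categories: dict[str, set[GeneId]] = {}
    for i, size in enumerate(cfg.category_sizes, start=1):
        idx = rng.choice(len(pool), size=size, replace=False)
        categories[f"pathway_{i:02d}"] = {pool[j] for j in idx}
    return AnnotationCollection(categories=categories, reference_total=len(pool))


def write_dataset(cfg: SynthConfig, out_dir) -> dict:
    """Emit a full synthetic dataset in the file dialects the pipeline
    reads, plus a ground-truth JSON; returns the ground-truth dict.

    Files: network.tsv (edge list), disease.tsv / drug.tsv (gene lists),
    annotations.gmt, regulation.tsv, truth.json.
    """
    import json
    from pathlib import Path

    from .network import write_edge_list
    from .signature_io import write_gene_list, write_gmt, write_regulation_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = make_network(cfg)
    disease, drug = make_signatures(cfg, net, truth)
    overlap = disease.genes & drug.genes
    regs = make_regulation(cfg, overlap)
    annotations = make_annotations(cfg)

    with open(out / "network.tsv", "w") as fh:
        write_edge_list(net, fh)
    # edge lists cannot carry degree-zero nodes; ship the universe explicitly
    with open(out / "universe.tsv", "w") as fh:
        write_gene_list(GeneSignature("universe", set(net.graph.nodes)), fh)
    with open(out / "disease.tsv", "w") as fh:
        write_gene_list(disease, fh)
    with open(out / "drug.tsv", "w") as fh:
        write_gene_list(drug, fh)
    with open(out / "annotations.gmt", "w") as fh:
        write_gmt(annotations, fh)
    with open(out / "regulation.tsv", "w") as fh:
        write_regulation_table(regs, fh)

    ground_truth = {
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "modules": [sorted(g.entrez for g in block) for block in truth],
        "disease_size": len(disease),
        "drug_size": len(drug),
        "overlap_size": len(overlap),
        "overlap": sorted(g.entrez for g in overlap),
        "discordant_fraction": cfg.discordant_fraction,
        "reference_total": annotations.reference_total,
    }
    (out / "truth.json").write_text(json.dumps(ground_truth, indent=2) + "\n")
    return ground_truth
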