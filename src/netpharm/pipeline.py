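"""End-to-end workflow orchestration behind a declarative YAML config.

Stages, in order: read signatures -> consolidate network -> map disease
signature and extract the induced subgraph -> MCODE segmentation ->
disease/drug interference (Fisher overlap) -> pathway over-representation
of the overlap genes -> regulation matching -> repurposing recommendation.
Stages whose inputs are absent (no annotations, no regulation table)
degrade gracefully: they are skipped and logged, never silently invented.

Every run writes TSV reports plus a JSON manifest echoing the full
configuration, input digests and per-stage counts, so the bookkeeping
identities (|members| + |isolated| + |unmapped| = |signature|) are
auditable after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment as enr
from . import matching as match_mod
from . import mcode
from . import network as netmod
from . import stats
from .signature_io import (
    GeneSignature,
    read_gene_list,
    read_gmt,
    read_regulation_table,
)

logger = logging.getLogger("netpharm.pipeline")

__all__ = ["RunManifest", "run_pipeline", "validate_config", "load_config"]


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    parameters: dict[str, Any]
    counts: dict[str, Any] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    started_at: float = 0.0
    finished_at: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


_REQUIRED = ("disease_signature", "drug_signature", "network")


def validate_config(config: dict[str, Any], base_dir: Path | None = None) -> list[str]:
    """Return a list of violations; empty means the config is runnable."""
    problems: list[str] = []
    base = base_dir or Path(".")
    for key in _REQUIRED:
        if key not in config:
            problems.append(f"missing mandatory key {key!r}")
    for key in ("disease_signature", "drug_signature", "annotations", "regulation"):
        if key in config and config[key]:
            p = base / config[key]
            if not p.exists():
                problems.append(f"{key}: file not found: {p}")
    net_cfg = config.get("network") or {}
    sources = net_cfg.get("sources") if isinstance(net_cfg, dict) else None
    if "network" in config and not sources:
        problems.append("network.sources: at least one edge-list source required")
    for src in sources or []:
        p = base / src.get("path", "")
        if not p.exists():
            problems.append(f"network source file not found: {p}")
    mc = config.get("mcode") or {}
    if "vwp" in mc and not 0.0 <= float(mc["vwp"]) < 1.0:
        problems.append(f"mcode.vwp: must be in [0, 1), got {mc['vwp']}")
    if "kcore_filter" in mc and int(mc["kcore_filter"]) < 2:
        problems.append("mcode.kcore_filter: must be >= 2")
    alpha = config.get("alpha", 0.05)
    if not 0.0 < float(alpha) < 1.0:
        problems.append(f"alpha: must be in (0, 1), got {alpha}")
    uni = config.get("universe", "network")
    if uni not in ("network", "file"):
        problems.append(f"universe: must be 'network' or 'file', got {uni!r}")
    if uni == "file" and "universe_file" not in config:
        problems.append("universe: 'file' requires universe_file")
    return problems


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _mcode_params(config: dict[str, Any]) -> mcode.MCODEParams:
    mc = config.get("mcode") or {}
    return mcode.MCODEParams(
        vwp=float(mc.get("vwp", 0.2)),
        haircut=bool(mc.get("haircut", True)),
        fluff=bool(mc.get("fluff", False)),
        fluff_density_threshold=float(mc.get("fluff_density_threshold", 0.1)),
        kcore_filter=int(mc.get("kcore_filter", 2)),
        max_depth=int(mc.get("max_depth", 100)),
    )


def run_pipeline(
    config: dict[str, Any], out_dir: str | Path, base_dir: str | Path = "."
) -> RunManifest:
    """Execute the full workflow; returns the run manifest.

    Raises ``ValueError`` (before any stage runs) when the config is
    invalid.
    """
    base = Path(base_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    problems = validate_config(config, base)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    params = _mcode_params(config)
    alpha = float(config.get("alpha", 0.05))
    two_sided = bool(config.get("two_sided", False))
    canonical = yaml.safe_dump(config, sort_keys=True)
    input_paths = {
        "disease_signature": base / config["disease_signature"],
        "drug_signature": base / config["drug_signature"],
    }
    for i, src in enumerate(config["network"]["sources"]):
        input_paths[f"network[{src.get('tag', i)}]"] = base / src["path"]
    for key in ("annotations", "regulation", "universe_file"):
        if config.get(key):
            input_paths[key] = base / config[key]

    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical.encode()).hexdigest()[:16],
        input_digests={k: _digest(p) for k, p in input_paths.items()},
        parameters={
            "mcode": asdict(params),
            "alpha": alpha,
            "two_sided": two_sided,
            "universe": config.get("universe", "network"),
            "bh_family": "tests run in this invocation",
        },
        started_at=time.time(),
    )

    def stage_done(name: str, **counts: Any) -> None:
        manifest.stages_completed.append(name)
        manifest.counts.update(counts)
        logger.info("stage %s done: %s", name, counts)

    # --- signatures ---------------------------------------------------
    with open(input_paths["disease_signature"]) as fh:
        disease = read_gene_list(fh, label="disease")
    with open(input_paths["drug_signature"]) as fh:
        drug = read_gene_list(fh, label="drug")
    stage_done("signatures", disease_size=len(disease), drug_size=len(drug))

    # --- network ------------------------------------------------------
    sources = []
    for src in config["network"]["sources"]:
        with open(base / src["path"]) as fh:
            pairs = netmod.read_edge_list(fh, default_tag=src.get("tag", "edges"))
        sources.extend(netmod.edges_by_source(pairs))
    net = netmod.consolidate(sources)
    stage_done("network", n_nodes=net.n_nodes, n_edges=net.n_edges)

    # --- induced subgraph --------------------------------------------
    sub = netmod.induced_subgraph(net, disease.genes)
    counts = sub.counts()
    assert counts["members"] + counts["isolated"] + counts["unmapped"] == len(disease)
    with open(out / "subgraph.tsv", "w") as fh:
        fh.write("gene\tstatus\n")
        for name, group in (
            ("member", sub.members),
            ("isolated", sub.isolated),
            ("unmapped", sub.unmapped),
        ):
            for g in sorted(group):
                fh.write(f"{g.entrez}\t{name}\n")
    stage_done("subgraph", **counts)

    # --- segmentation -------------------------------------------------
    segments = mcode.predict_complexes(sub.graph, params)
    summary = mcode.segment_summary(segments)
    summary.table.to_csv(out / "segments.tsv", sep="\t", index=False)
    stage_done(
        "segmentation",
        n_segments=summary.n_segments,
        segment_gene_total=summary.n_genes,
        min_segment_size=summary.min_size,
        max_segment_size=summary.max_size,
    )

    # --- interference -------------------------------------------------
    if config.get("universe", "network") == "file":
        with open(input_paths["universe_file"]) as fh:
            universe = read_gene_list(fh, label="universe").genes
    else:
        universe = net.nodes
    overlap = stats.interfere(disease, drug, universe, alpha=alpha, two_sided=two_sided)
    seg_map = stats.segment_overlap_map(segments, drug)
    seg_members = {g: s.segment_id for s in segments for g in s.members}
    with open(out / "interference.tsv", "w") as fh:
        a, b, c, d = overlap.table
        fh.write(f"# a={a}\tb={b}\tc={c}\td={d}\tp_raw={overlap.p_raw:.6g}"
                 f"\tp_adjusted={overlap.p_adjusted:.6g}\tsignificant={int(overlap.significant)}\n")
        fh.write("gene\tsegment\n")
        for g in sorted(overlap.overlap):
            fh.write(f"{g.entrez}\t{seg_members.get(g, '')}\n")
        fh.write("# per-segment overlap\n")
        fh.write("segment_id\tn_shared\tshared\n")
        for so in seg_map.overlaps:
            genes = ",".join(str(g.entrez) for g in sorted(so.shared))
            fh.write(f"{so.segment_id}\t{so.n_shared}\t{genes}\n")
    stage_done(
        "interference",
        overlap_size=len(overlap.overlap),
        p_raw=overlap.p_raw,
        significant=overlap.significant,
        overlap_in_segments=seg_map.total_shared,
        max_segment_share=seg_map.max_shared,
    )

    # --- enrichment ---------------------------------------------------
    if config.get("annotations"):
        with open(input_paths["annotations"]) as fh:
            annotations = read_gmt(fh, reference_total=config.get("reference_total"))
        rows = enr.enrich(overlap.overlap, annotations)
        with open(out / "enrichment.tsv", "w") as fh:
            enr.write_enrichment_table(rows, fh)
        stage_done("enrichment", n_categories=len(rows))
    else:
        logger.info("stage enrichment skipped: no annotations configured")

    # --- matching -----------------------------------------------------
    if config.get("regulation"):
        with open(input_paths["regulation"]) as fh:
            regs = read_regulation_table(fh)
        report = match_mod.match_segment_genes(segments, overlap.overlap, regs)
        recommendation = match_mod.repurposing_summary(report)
        with open(out / "matching.tsv", "w") as fh:
            match_mod.write_match_table(report, recommendation, fh)
        stage_done(
            "matching",
            n_discordant=report.n_discordant,
            n_concordant=report.n_concordant,
            n_ambiguous=report.n_ambiguous,
            n_unknown=report.n_unknown,
            recommendation=recommendation.value,
        )
    else:
        logger.info("stage matching skipped: no regulation table configured")

    manifest.finished_at = time.time()
    manifest.write(out / "manifest.json")
    return manifest
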