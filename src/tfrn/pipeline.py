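"""End-to-end orchestration: enrichment → classification → network.

The pipeline is deterministic: the same configuration and inputs always
produce identical outputs (the only randomness in the package lives in the
synthetic-fixture generator and is seeded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from tfrn import classification as _classify
from tfrn import enrichment as _enrich
from tfrn import network as _network
from tfrn.genomic_io import (
    DEGTable,
    InputError,
    PeakSet,
    PromoterRegion,
    extract_promoters,
    load_deg_lists,
    load_peak_manifest,
    load_tss_annotation,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable knobs of a network-reconstruction run.

    Defaults follow the reference protocol: 1000 bp promoters upstream of
    the TSS, any (>= 1 bp) peak overlap, BH FDR at 0.001 pooled over the
    whole run, inclusive tier-2 rule, most-upstream representative TSS.
    """

    annotation_path: Optional[str] = None
    annotation_format: str = "tsv"
    manifest_path: Optional[str] = None
    library_label: Optional[str] = None
    upstream_len: int = 1000
    min_overlap_bp: int = 1
    fdr_alpha: float = 0.001
    bh_pool: str = "run"  # or per-direction
    tier2_rule: str = "any-parent"  # or all-parents
    tss_rule: str = "most-upstream"  # or first-listed
    output_dir: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    enrichment_records: list
    classifications: list
    network_classes: list
    links: list
    graph: nx.DiGraph
    config: PipelineConfig = field(default_factory=PipelineConfig)


def run_pipeline_from_objects(
    promoters: Sequence[PromoterRegion],
    peaksets: Sequence[PeakSet],
    deg_table: DEGTable,
    config: Optional[PipelineConfig] = None,
    universe: Optional[set[str]] = None,
) -> PipelineResult:
    """Run enrichment → classification → network on in-memory inputs."""
    cfg = config or PipelineConfig()
    if cfg.library_label is not None:
        peaksets = [ps for ps in peaksets if ps.library_label == cfg.library_label]
        if not peaksets:
            raise InputError(f"no peak sets with library label {cfg.library_label!r}")
    records = _enrich.run_enrichment(
        promoters,
        peaksets,
        deg_table,
        universe=universe,
        alpha=cfg.fdr_alpha,
        min_overlap_bp=cfg.min_overlap_bp,
        bh_pool=cfg.bh_pool,
    )
    classifications = _classify.classify_all(records, deg_table)
    network_classes = _classify.retain_network_classes(classifications)
    links = _network.infer_links(
        network_classes, promoters, peaksets, min_overlap_bp=cfg.min_overlap_bp
    )
    graph = _network.build_graph(network_classes, links)
    _network.assign_tiers(graph, tier2_rule=cfg.tier2_rule)
    problems = _network.audit_graph(graph)
    if problems:  # defensive: audit should never fire on internally built graphs
        raise RuntimeError("graph audit failed: " + "; ".join(problems))
    return PipelineResult(records, classifications, network_classes, links, graph, cfg)


def run_pipeline(config: PipelineConfig, deg_table: Optional[DEGTable] = None,
                 up_path: Optional[str] = None, down_path: Optional[str] = None,
                 deg_csv: Optional[str] = None) -> PipelineResult:
    """Run the full pipeline from files named in the config."""
    if config.annotation_path is None or config.manifest_path is None:
        raise InputError("config requires annotation_path and manifest_path")
    tss = load_tss_annotation(
        config.annotation_path, format=config.annotation_format, tss_rule=config.tss_rule
    )
    promoters = extract_promoters(tss, upstream_len=config.upstream_len)
    peaksets = load_peak_manifest(config.manifest_path)
    if deg_table is None:
        deg_table = load_deg_lists(up_path, down_path, combined_path=deg_csv)
    return run_pipeline_from_objects(promoters, peaksets, deg_table, config)


def write_run_manifest(result: PipelineResult, out_dir: str | Path,
                       input_paths: Sequence[str | Path] = ()) -> Path:
    """Record config hash and input checksums for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    checksums = {}
    for p in input_paths:
        p = Path(p)
        if p.exists():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "config": cfg,
        "config_hash": cfg_hash,
        "input_checksums": checksums,
        "counts": {
            "enrichment_tests": len(result.enrichment_records),
            "enriched": sum(r.enriched for r in result.enrichment_records),
            "classified_tfs": len(result.classifications),
            "network_tfs": len(result.network_classes),
            "links": len(result.links),
        },
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
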