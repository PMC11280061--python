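"""Signed regulator→target network construction (step 3).

A link runs from TF1 (regulator) to TF2 (target) when a TF1 binding peak
lies in the promoter of the TF2 coding gene. The link sign follows the
regulator's predicted function: activation for DA/UA, inhibition for DS/US.

Of the 16 ordered class pairs only eight are mechanistically meaningful:
an activator may only target genes co-directional with its own coding gene
(an upregulated activator explains upregulated targets), and a suppressor
may only target genes of the opposite direction. The admissible set is
UA–UA, UA–US, DS–UA, DS–US, US–DA, US–DS, DA–DA, DA–DS.

Nodes split into a stimulus-repressed R-subnetwork (DA, DS — active before
the stimulus, switched off by it) and a stimulus-activated A-subnetwork
(UA, US). Within the DA–DA core three tiers are assigned: tier 1 nodes have
only outgoing DA–DA arcs (self-loops excluded from in-degree), tier 2 nodes
are triggered by tier-1 nodes, tier 3 combines the rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from tfrn.classification import NETWORK_CLASSES, TFClassification
from tfrn.enrichment import genes_bound
from tfrn.genomic_io import InputError, PeakInterval, PeakSet, PromoterRegion

logger = logging.getLogger(__name__)

#: The eight mechanistically meaningful (regulator, target) class pairs.
MEANINGFUL_PAIRS = frozenset(
    {
        ("UA", "UA"),
        ("UA", "US"),
        ("DS", "UA"),
        ("DS", "US"),
        ("US", "DA"),
        ("US", "DS"),
        ("DA", "DA"),
        ("DA", "DS"),
    }
)

ACTIVATOR_CLASSES = ("DA", "UA")

#: Direction of the coding gene for each network class.
CLASS_GENE_DIRECTION = {"DA": "down", "DS": "down", "US": "up", "UA": "up"}


@dataclass(frozen=True)
class RegulatoryLink:
    regulator: str
    target: str
    sign: str  # activation / inhibition
    regulator_class: str
    target_class: str
    supporting_peaks: tuple[tuple[str, PeakInterval], ...] = field(default_factory=tuple)


def is_meaningful_pair(regulator_class: str, target_class: str) -> bool:
    """Whether a (regulator, target) class pair is sign-consistent.

    Equivalent formulation: activators (DA, UA) may target genes
    co-directional with their own coding gene; suppressors (DS, US) may
    target genes of the opposite direction.
    """
    for cls in (regulator_class, target_class):
        if cls not in NETWORK_CLASSES:
            raise InputError(f"{cls!r} is not one of the four network classes")
    return (regulator_class, target_class) in MEANINGFUL_PAIRS


def link_sign(regulator_class: str) -> str:
    return "activation" if regulator_class in ACTIVATOR_CLASSES else "inhibition"


def infer_links(
    classified: Sequence[TFClassification],
    promoters: Sequence[PromoterRegion],
    peaksets: Iterable[PeakSet],
    min_overlap_bp: int = 1,
) -> list[RegulatoryLink]:
    """Infer regulator→target links among the four-class TFs.

    A link is emitted iff a regulator peak overlaps the target TF's promoter
    by >= min_overlap_bp AND the class pair is meaningful. Multiple
    supporting peaks or peak sets collapse to one unweighted link carrying
    the evidence list. Self-links arise only for DA–DA and UA–UA (the only
    meaningful same-class pairs).
    """
    class_of = {c.tf_gene_id: c.tf_class for c in classified}
    bad = [tf for tf, cls in class_of.items() if cls not in NETWORK_CLASSES]
    if bad:
        raise InputError(f"non-network classes passed to infer_links: {bad}")

    prom_by_gene = {p.gene_id: p for p in promoters}
    missing = sorted(set(class_of) - set(prom_by_gene))
    if missing:
        logger.warning(
            "%d target TF genes lack a promoter; no links to them: %s",
            len(missing),
            ", ".join(missing),
        )
    target_promoters = [prom_by_gene[tf] for tf in sorted(class_of) if tf in prom_by_gene]

    evidence: dict[tuple[str, str], list[tuple[str, PeakInterval]]] = {}
    for ps in peaksets:
        reg = ps.tf_gene_id
        if reg not in class_of:
            continue
        bound = genes_bound(target_promoters, ps, min_overlap_bp=min_overlap_bp)
        for target in bound:
            if not is_meaningful_pair(class_of[reg], class_of[target]):
                continue
            prom = prom_by_gene[target]
            support = [
                (ps.library_label, pk)
                for pk in ps.peaks
                if pk.chrom == prom.chrom
                and min(pk.end, prom.end) - max(pk.start, prom.start) >= min_overlap_bp
            ]
            evidence.setdefault((reg, target), []).extend(support)

    links = [
        RegulatoryLink(
            regulator=reg,
            target=tgt,
            sign=link_sign(class_of[reg]),
            regulator_class=class_of[reg],
            target_class=class_of[tgt],
            supporting_peaks=tuple(sorted(sup, key=lambda s: (s[0], s[1].start))),
        )
        for (reg, tgt), sup in sorted(evidence.items())
    ]
    logger.info("link inference: %d links among %d classified TFs", len(links), len(class_of))
    return links


def build_graph(
    classified: Sequence[TFClassification],
    links: Sequence[RegulatoryLink],
) -> nx.DiGraph:
    """Assemble the TFRN as a networkx DiGraph with class/sign attributes.

    All classified TFs become nodes (isolated ones included and flagged);
    subnetwork and tier labels are attached by :func:`partition_subnetworks`
    and :func:`assign_tiers`.
    """
    g = nx.DiGraph()
    for c in sorted(classified, key=lambda x: x.tf_gene_id):
        g.add_node(c.tf_gene_id, tf_class=c.tf_class, tier=0)
    for ln in links:
        g.add_edge(
            ln.regulator,
            ln.target,
            sign=ln.sign,
            n_supporting_peaks=len(ln.supporting_peaks),
        )
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    partition_subnetworks(g)
    assign_tiers(g)
    return g


def partition_subnetworks(graph: nx.DiGraph) -> nx.DiGraph:
    """Label nodes R/A and edges by the subnetworks they connect.

    R-subnetwork = {DA, DS} (operates before the stimulus), A-subnetwork =
    {UA, US} (switched on by it). Edge kinds: within-R, within-A, A->R
    (US–DA, US–DS) and R->A (DS–UA, DS–US).
    """
    for node, data in graph.nodes(data=True):
        data["subnetwork"] = "R" if data["tf_class"] in ("DA", "DS") else "A"
    for u, v, data in graph.edges(data=True):
        su, sv = graph.nodes[u]["subnetwork"], graph.nodes[v]["subnetwork"]
        if su == sv:
            data["kind"] = f"within-{su}"
        else:
            data["kind"] = f"{su}->{sv}"
    return graph


def assign_tiers(graph: nx.DiGraph, tier2_rule: str = "any-parent") -> nx.DiGraph:
    """Three-tier hierarchy over the DA–DA core.

    Considering only edges between DA nodes (the core), with self-loops
    excluded from in-degree: tier 1 = core nodes with no incoming core edge;
    tier 2 = core nodes triggered by tier 1 (``any-parent``: >= 1 incoming
    edge from tier 1; ``all-parents``: every incoming core edge from tier 1);
    tier 3 = the remaining core nodes. Nodes outside the core get tier 0
    ("none"). A core made only of cycles has no tier-1 seed; all its nodes
    fall to tier 3 with a warning.
    """
    if tier2_rule not in ("any-parent", "all-parents"):
        raise InputError(f"unknown tier2_rule: {tier2_rule}")
    da_nodes = {n for n, d in graph.nodes(data=True) if d["tf_class"] == "DA"}
    core_edges = [
        (u, v) for u, v in graph.edges if u in da_nodes and v in da_nodes
    ]
    core_nodes = {u for u, v in core_edges} | {v for u, v in core_edges}

    incoming: dict[str, set[str]] = {n: set() for n in core_nodes}
    for u, v in core_edges:
        if u != v:  # self-regulation excluded from in-degree
            incoming[v].add(u)

    tier1 = {n for n in core_nodes if not incoming[n]}
    if core_nodes and not tier1:
        logger.warning("DA–DA core is purely cyclic: no tier-1 seed; all tier 3")
    rest = core_nodes - tier1
    if tier2_rule == "any-parent":
        tier2 = {n for n in rest if incoming[n] & tier1}
    else:
        tier2 = {n for n in rest if incoming[n] and incoming[n] <= tier1}
    tier3 = rest - tier2

    for node, data in graph.nodes(data=True):
        if node in tier1:
            data["tier"] = 1
        elif node in tier2:
            data["tier"] = 2
        elif node in tier3:
            data["tier"] = 3
        else:
            data["tier"] = 0
    return graph


def audit_graph(graph: nx.DiGraph) -> list[str]:
    """Post-export audit: return invariant violations (empty list = clean).

    Checks the sign/class invariant on every edge, the meaningful-pair
    predicate, the subnetwork labeling, and the tier partition of the
    DA–DA core.
    """
    problems = []
    for u, v, data in graph.edges(data=True):
        cu = graph.nodes[u]["tf_class"]
        cv = graph.nodes[v]["tf_class"]
        if not is_meaningful_pair(cu, cv):
            problems.append(f"edge {u}->{v}: pair ({cu},{cv}) not meaningful")
        want = link_sign(cu)
        if data.get("sign") != want:
            problems.append(f"edge {u}->{v}: sign {data.get('sign')} != {want}")
    for n, data in graph.nodes(data=True):
        want = "R" if data["tf_class"] in ("DA", "DS") else "A"
        if data.get("subnetwork") != want:
            problems.append(f"node {n}: subnetwork {data.get('subnetwork')} != {want}")
    da = {n for n, d in graph.nodes(data=True) if d["tf_class"] == "DA"}
    core = {
        n
        for u, v in graph.edges
        if u in da and v in da
        for n in (u, v)
    }
    for n in core:
        if graph.nodes[n]["tier"] not in (1, 2, 3):
            problems.append(f"core node {n} lacks a tier")
    for n in set(graph.nodes) - core:
        if graph.nodes[n]["tier"] != 0:
            problems.append(f"non-core node {n} carries tier {graph.nodes[n]['tier']}")
    return problems


def _write_dot(graph: nx.DiGraph, path: Path) -> None:
    # minimal DOT writer: deterministic, attribute-preserving for sign/class
    with open(path, "w") as fh:
        fh.write("digraph TFRN {\n")
        for n in sorted(graph.nodes):
            d = graph.nodes[n]
            fh.write(
                f'  "{n}" [tf_class="{d["tf_class"]}" subnetwork="{d["subnetwork"]}"'
                f' tier="{d["tier"]}"];\n'
            )
        for u, v in sorted(graph.edges):
            d = graph.edges[u, v]
            arrow = "normal" if d["sign"] == "activation" else "tee"
            fh.write(f'  "{u}" -> "{v}" [sign="{d["sign"]}" arrowhead={arrow}];\n')
        fh.write("}\n")


def export_graph(graph: nx.DiGraph, path: str | Path, format: str = "graphml") -> Path:
    """Serialize the network deterministically (nodes/edges sorted by id).

    Formats: graphml, json (node-link), dot, tsv-edgelist.
    """
    path = Path(path)
    ordered = nx.DiGraph()
    ordered.add_nodes_from(sorted(graph.nodes(data=True)))
    ordered.add_edges_from(
        (u, v, graph.edges[u, v]) for u, v in sorted(graph.edges)
    )
    if format == "graphml":
        nx.write_graphml(ordered, path)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(nx.node_link_data(ordered, edges="edges"), fh, indent=1, sort_keys=True)
    elif format == "dot":
        _write_dot(ordered, path)
    elif format == "tsv-edgelist":
        with open(path, "w") as fh:
            fh.write("regulator\ttarget\tsign\tn_supporting_peaks\n")
            for u, v in sorted(ordered.edges):
                d = ordered.edges[u, v]
                fh.write(
                    f"{u}\t{v}\t{d['sign']}\t{d.get('n_supporting_peaks', 0)}\n"
                )
    else:
        raise InputError(f"unknown export format: {format}")
    return path


def compare_link_sets(
    links_a: Iterable[tuple[str, str] | RegulatoryLink],
    links_b: Iterable[tuple[str, str] | RegulatoryLink],
) -> tuple[set[tuple[str, str]], set[tuple[str, str]], set[tuple[str, str]]]:
    """Set comparison of two link collections as (regulator, target) pairs.

    Returns (only_a, only_b, common), ignoring supporting-peak evidence.
    Used e.g. to contrast networks built from different peak libraries.
    """

    def as_pairs(links):
        return {
            (ln.regulator, ln.target) if isinstance(ln, RegulatoryLink) else tuple(ln)
            for ln in links
        }

    pa, pb = as_pairs(links_a), as_pairs(links_b)
    return pa - pb, pb - pa, pa & pb


def robustness_sweep(
    deg_table,
    fc_thresholds: Sequence[float],
    config,
    promoters: Optional[Sequence[PromoterRegion]] = None,
    peaksets: Optional[Sequence[PeakSet]] = None,
):
    """Re-run the pipeline at increasing |log2fc| DEG-calling thresholds.

    Returns a TF x threshold boolean DataFrame: True where the TF is a node
    of the network at that threshold. Thresholds that filter out all DEGs
    yield an all-False column with a warning.
    """
    import pandas as pd

    from tfrn.pipeline import run_pipeline_from_objects

    presence: dict[float, set[str]] = {}
    all_tfs: set[str] = set()
    for t in fc_thresholds:
        sub = deg_table.filter_by_fc(t)
        if not len(sub.frame):
            logger.warning("threshold %g removes every DEG", t)
            presence[t] = set()
            continue
        result = run_pipeline_from_objects(promoters, peaksets, sub, config)
        nodes = set(result.graph.nodes)
        presence[t] = nodes
        all_tfs |= nodes
    tfs = sorted(all_tfs)
    return pd.DataFrame(
        {t: [tf in presence[t] for tf in tfs] for t in fc_thresholds},
        index=tfs,
    )
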