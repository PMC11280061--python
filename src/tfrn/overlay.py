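"""Overlay of network regulators onto arbitrary gene lists.

Two reports: which regulators bind each gene of a list (e.g. the genes of
an enriched biological process), and how regulator peaks stack within one
target promoter, in TSS-relative coordinates (negative = upstream, so a
promoter of length L spans [-L, 0) regardless of strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from tfrn.classification import TFClassification
from tfrn.enrichment import genes_bound
from tfrn.genomic_io import InputError, PeakSet, PromoterRegion

logger = logging.getLogger(__name__)

#: Classes that explain downregulated targets (active-before DA loses its
#: activation; stimulus-induced US actively represses) and upregulated ones.
DOWN_TARGET_CLASSES = ("DA", "US")
UP_TARGET_CLASSES = ("UA", "DS")


@dataclass
class TargetReport:
    gene_list_name: str
    regulators_by_gene: dict[str, list[tuple[str, str]]]  # gene -> [(tf, class)]
    class_fractions: dict[str, float]
    regulator_target_counts: dict[str, int]
    unresolved: list[str] = field(default_factory=list)


@dataclass
class CoBindingCluster:
    target_gene_id: str
    # regulator -> list of TSS-relative half-open intervals
    relative_peaks: dict[str, list[tuple[int, int]]]
    # overlap groups: transitive closure of pairwise interval overlap
    groups: list[set[str]]


def tf_targets_for_genes(
    gene_list: Sequence[str],
    regulators: Sequence[TFClassification],
    promoters: Sequence[PromoterRegion],
    peaksets: Iterable[PeakSet],
    direction_filter: Optional[str] = None,
    gene_list_name: str = "gene_list",
    min_overlap_bp: int = 1,
) -> TargetReport:
    """Report which regulators bind the promoters of a gene list.

    ``direction_filter`` restricts regulators by the direction of change
    their class explains: "down" keeps DA/US, "up" keeps UA/DS (matching a
    down- or upregulated gene list). Duplicate gene ids are deduplicated;
    ids without a promoter are reported as unresolved.
    """
    genes = sorted(dict.fromkeys(gene_list))
    if not genes:
        raise InputError("empty gene list")
    if direction_filter not in (None, "up", "down"):
        raise InputError(f"invalid direction_filter: {direction_filter!r}")

    keep_classes = {
        None: set(DOWN_TARGET_CLASSES) | set(UP_TARGET_CLASSES),
        "down": set(DOWN_TARGET_CLASSES),
        "up": set(UP_TARGET_CLASSES),
    }[direction_filter]
    regs = [r for r in regulators if r.tf_class in keep_classes]

    prom_by_gene = {p.gene_id: p for p in promoters}
    resolvable = [g for g in genes if g in prom_by_gene]
    unresolved = [g for g in genes if g not in prom_by_gene]
    if unresolved:
        logger.warning("%d gene-list ids lack a promoter: %s",
                       len(unresolved), ", ".join(unresolved[:5]))
    target_proms = [prom_by_gene[g] for g in resolvable]

    sets_by_tf: dict[str, list[PeakSet]] = {}
    for ps in peaksets:
        sets_by_tf.setdefault(ps.tf_gene_id, []).append(ps)

    regulators_by_gene: dict[str, list[tuple[str, str]]] = {g: [] for g in resolvable}
    reg_counts: dict[str, int] = {}
    for reg in sorted(regs, key=lambda r: r.tf_gene_id):
        bound: set[str] = set()
        for ps in sets_by_tf.get(reg.tf_gene_id, []):
            bound |= genes_bound(target_proms, ps, min_overlap_bp=min_overlap_bp)
        reg_counts[reg.tf_gene_id] = len(bound)
        for g in bound:
            regulators_by_gene[g].append((reg.tf_gene_id, reg.tf_class))

    n = len(resolvable)
    fractions = {}
    for cls in sorted(keep_classes):
        hit = sum(
            1
            for g in resolvable
            if any(c == cls for _, c in regulators_by_gene[g])
        )
        fractions[cls] = hit / n if n else 0.0
    return TargetReport(
        gene_list_name=gene_list_name,
        regulators_by_gene=regulators_by_gene,
        class_fractions=fractions,
        regulator_target_counts=reg_counts,
        unresolved=unresolved,
    )


def _relative_interval(
    peak_start: int, peak_end: int, prom: PromoterRegion
) -> tuple[int, int]:
    """Clip a genomic peak to the promoter and express it TSS-relative.

    Upstream is negative on both strands: base at distance d upstream of the
    TSS maps to coordinate -d, so every promoter spans [-L, 0).
    """
    s = max(peak_start, prom.start)
    e = min(peak_end, prom.end)
    if prom.strand == "+":
        tss = prom.end  # promoter is [tss - L, tss)
        return s - tss, e - tss
    tss = prom.start - 1  # promoter is [tss + 1, tss + 1 + L)
    # genomic base g (> tss) lies g - tss bp upstream -> coordinate tss - g
    return tss - (e - 1), tss - s + 1


def co_binding_report(
    target_gene: str,
    regulators: Sequence[TFClassification],
    promoters: Sequence[PromoterRegion],
    peaksets: Iterable[PeakSet],
) -> CoBindingCluster:
    """Peak stacking of the regulators within one target promoter.

    Each regulator peak intersecting the promoter is converted to
    TSS-relative coordinates; regulators are grouped by the transitive
    closure of pairwise interval overlap (union-find), so a chain
    a∩b, b∩c puts a, b, c in one group even if a and c are disjoint.
    """
    prom = next((p for p in promoters if p.gene_id == target_gene), None)
    if prom is None:
        raise InputError(f"{target_gene} has no promoter")
    reg_ids = {r.tf_gene_id for r in regulators}

    relative: dict[str, list[tuple[int, int]]] = {}
    entries: list[tuple[str, int, int]] = []  # one entry per peak
    for ps in peaksets:
        if ps.tf_gene_id not in reg_ids:
            continue
        for pk in ps.peaks:
            if pk.chrom != prom.chrom:
                continue
            if min(pk.end, prom.end) - max(pk.start, prom.start) >= 1:
                rs, re = _relative_interval(pk.start, pk.end, prom)
                relative.setdefault(ps.tf_gene_id, []).append((rs, re))
                entries.append((ps.tf_gene_id, rs, re))
    for v in relative.values():
        v.sort()

    # union-find over peak entries
    parent = list(range(len(entries)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            _, s1, e1 = entries[i]
            _, s2, e2 = entries[j]
            if min(e1, e2) - max(s1, s2) >= 1:
                union(i, j)

    by_root: dict[int, set[str]] = {}
    for i, (tf, _, _) in enumerate(entries):
        by_root.setdefault(find(i), set()).add(tf)
    groups = sorted(by_root.values(), key=lambda g: sorted(g))
    return CoBindingCluster(target_gene, relative, groups)
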