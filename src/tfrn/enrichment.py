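"""Binding-site enrichment in DEG promoters (step 1).

For each TF peak set and each DEG direction, the 2x2 contingency table

===========  ===============  ==================
 .           promoter bound   promoter not bound
DEG gene     a                b
non-DEG      c                d
===========  ===============  ==================

is tested one-sided for enrichment with Fisher's exact test: the p-value is
the upper hypergeometric tail ``P(X >= a)`` with ``X ~ Hypergeom(N=a+b+c+d,
K=a+c, n=a+b)``. A one-sided test is used because the downstream TF
classification can only interpret enrichment, not depletion. All tests of
one run (every peak set of the selected library x both DEG directions) are
pooled for Benjamini-Hochberg FDR control; per-direction pooling is
available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from tfrn.genomic_io import DEGTable, InputError, PeakSet, PromoterRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """Gene counts for one (peak set, DEG direction) test.

    a: DEG genes whose promoter overlaps >= 1 peak
    b: DEG genes with no overlapping peak
    c: non-DEG universe genes with >= 1 peak
    d: non-DEG universe genes with no peak
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError(f"negative contingency cell: {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Result of one enrichment test, with BH-adjusted q-value."""

    tf_gene_id: str
    library_label: str
    peakset_name: str
    deg_direction: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    q_value: float
    enriched: bool


def genes_bound(
    promoters: Sequence[PromoterRegion],
    peakset: PeakSet,
    min_overlap_bp: int = 1,
) -> set[str]:
    """Genes whose promoter is overlapped by >= min_overlap_bp of any peak.

    Binarized: peak multiplicity within one promoter does not matter. A
    warning reports chromosome-name dialects that cannot match (e.g. "chr1"
    in peaks vs "1" in the annotation).
    """
    if min_overlap_bp < 1:
        raise InputError("min_overlap_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for peak in peakset.peaks:
        trees.setdefault(peak.chrom, IntervalTree()).addi(peak.start, peak.end)

    promoter_chroms = {p.chrom for p in promoters}
    if peakset.peaks and promoters and not (set(trees) & promoter_chroms):
        tally = Counter(p.chrom for p in peakset.peaks)
        logger.warning(
            "no chromosome shared between promoters %s and peak set %s %s",
            sorted(promoter_chroms),
            peakset.name,
            dict(tally),
        )

    bound: set[str] = set()
    for prom in promoters:
        tree = trees.get(prom.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(prom.start, prom.end):
            overlap = min(iv.end, prom.end) - max(iv.begin, prom.start)
            if overlap >= min_overlap_bp:
                bound.add(prom.gene_id)
                break
    return bound


def build_contingency(
    deg_genes: set[str],
    bound_genes: set[str],
    universe: set[str],
) -> ContingencyTable:
    """Build the 2x2 table by set arithmetic over the gene universe.

    DEG and bound genes outside the universe are dropped (reported at debug
    level); the table margins then satisfy a+b = |DEG ∩ universe| and
    a+b+c+d = |universe|.
    """
    if not universe:
        raise InputError("empty gene universe")
    dropped = deg_genes - universe
    if dropped:
        logger.debug("%d DEG genes outside universe dropped", len(dropped))
    deg = deg_genes & universe
    bound = bound_genes & universe
    a = len(deg & bound)
    b = len(deg - bound)
    c = len(bound - deg)
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_pvalue(table: ContingencyTable) -> float:
    """One-sided (greater) Fisher exact p: the upper hypergeometric tail.

    ``P(X >= a)`` for ``X ~ Hypergeom(N=total, K=a+c, n=a+b)``. Degenerate
    margins (a = 0, empty rows/columns) give p = 1.
    """
    n_total = table.total
    k_bound = table.a + table.c
    n_deg = table.a + table.b
    # sf(a-1) = P(X >= a); exact for a = 0 too (whole support, p = 1)
    p = float(hypergeom.sf(table.a - 1, n_total, k_bound, n_deg))
    return min(p, 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    if len(pvalues) == 0:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise InputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in q]


def run_enrichment(
    promoters: Sequence[PromoterRegion],
    peaksets: Iterable[PeakSet],
    deg_table: DEGTable,
    universe: Optional[set[str]] = None,
    alpha: float = 0.001,
    min_overlap_bp: int = 1,
    bh_pool: str = "run",
) -> list[EnrichmentRecord]:
    """Test every (peak set x DEG direction) of one library for enrichment.

    Parameters
    ----------
    promoters
        Promoter regions of the gene universe (genes without a mappable
        promoter are excluded from the tables).
    peaksets
        Peak sets, all of one library label (mixing labels is an error —
        libraries are processed in separate runs).
    universe
        Background gene set; defaults to all genes with a promoter.
    alpha
        FDR level; a record is ``enriched`` iff q <= alpha.
    bh_pool
        "run" pools all tests of the run for BH (default); "per-direction"
        adjusts up- and down-tests separately.
    """
    peaksets = list(peaksets)
    labels = {ps.library_label for ps in peaksets}
    if len(labels) > 1:
        raise InputError(
            f"peak sets span several libraries {sorted(labels)}; run each separately"
        )
    if bh_pool not in ("run", "per-direction"):
        raise InputError(f"unknown bh_pool: {bh_pool}")

    if universe is None:
        universe = {p.gene_id for p in promoters}
    else:
        promoter_genes = {p.gene_id for p in promoters}
        unmapped = universe - promoter_genes
        if unmapped:
            logger.warning(
                "%d universe genes lack a mappable promoter; excluded", len(unmapped)
            )
        universe = universe & promoter_genes
    prom_in_universe = [p for p in promoters if p.gene_id in universe]

    tests: list[tuple[PeakSet, str, ContingencyTable]] = []
    for ps in sorted(peaksets, key=lambda s: (s.tf_gene_id, s.name or "")):
        bound = genes_bound(prom_in_universe, ps, min_overlap_bp=min_overlap_bp)
        for direction in ("up", "down"):
            table = build_contingency(deg_table.genes(direction), bound, universe)
            tests.append((ps, direction, table))

    pvals = [fisher_pvalue(t) for _, _, t in tests]
    if bh_pool == "run":
        qvals = bh_adjust(pvals)
    else:
        qvals = [0.0] * len(pvals)
        for direction in ("up", "down"):
            idx = [i for i, (_, d, _) in enumerate(tests) if d == direction]
            sub_q = bh_adjust([pvals[i] for i in idx])
            for i, q in zip(idx, sub_q):
                qvals[i] = q

    records = [
        EnrichmentRecord(
            tf_gene_id=ps.tf_gene_id,
            library_label=ps.library_label,
            peakset_name=ps.name or "",
            deg_direction=direction,
            table=table,
            odds_ratio=table.odds_ratio,
            p_value=p,
            q_value=q,
            enriched=q <= alpha,
        )
        for (ps, direction, table), p, q in zip(tests, pvals, qvals)
    ]
    n_enr = sum(r.enriched for r in records)
    logger.info(
        "enrichment: %d tests (%d peak sets x 2 directions), %d enriched at FDR %g",
        len(records),
        len(peaksets),
        n_enr,
        alpha,
    )
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]):
    """Tidy DataFrame of enrichment records (for TSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tf_gene_id": r.tf_gene_id,
                "library_label": r.library_label,
                "peakset_name": r.peakset_name,
                "direction": r.deg_direction,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "enriched": r.enriched,
            }
            for r in records
        ]
    )
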