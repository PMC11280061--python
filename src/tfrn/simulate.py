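"""Planted-network simulator: ground-truth fixtures for the whole pipeline.

The generator lays genes on a synthetic chromosome with promoters spaced so
far apart that no peak can ambiguously support two genes, makes each TF's
coding gene a DEG of the direction its planted class dictates, realizes
every planted regulator→target edge as a peak inside the target's promoter,
and salts enough additional DEG-promoter peaks that the one-sided Fisher
q-value provably clears the FDR level — the salt count is computed from the
exact hypergeometric tail with a safety margin, never guessed, and every
planted (TF, direction) test is re-verified with the enrichment module's
own :func:`~tfrn.enrichment.fisher_pvalue` before any file is written.

Noise comes in two calibrated forms: intergenic peaks that by construction
cannot touch a promoter, and spurious promoter hits placed in
wrong-direction DEG promoters in numbers verified to keep the corresponding
test non-significant — so the recovered topology is unchanged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from tfrn.genomic_io import InputError
from tfrn.network import MEANINGFUL_PAIRS

logger = logging.getLogger(__name__)

#: DEG direction implied by each planted class for the TF's own coding gene.
CLASS_GENE_DIR = {
    "DA": "down", "DS": "down", "DR": "down",
    "UA": "up", "US": "up", "UR": "up",
    "NTR": "none",
}

#: DEG direction(s) whose promoters each planted class is enriched in.
CLASS_ENRICH_DIRS = {
    "DA": ("down",), "US": ("down",),
    "UA": ("up",), "DS": ("up",),
    "DR": ("up", "down"), "UR": ("up", "down"),
    "NTR": ("down",),  # enriched somewhere, gene not a DEG
}


@dataclass
class PlantedNetwork:
    """Specification of a ground-truth network and its genomic realization."""

    tfs: list[tuple[str, str]]  # (tf_gene_id, planted_class)
    edges: list[tuple[str, str]]  # (regulator, target), meaningful pairs only
    n_up: int = 60
    n_down: int = 60
    n_neutral: int = 70
    upstream_len: int = 1000
    alpha: float = 0.001
    library_label: str = "col"
    peak_width: int = 200
    gene_spacing: int = 3000
    salt_safety: float = 50.0  # margin factor on alpha/m for the salted tail
    noise_intergenic: int = 0  # noise peaks per TF, outside all promoters
    noise_promoter_hits: int = 0  # spurious wrong-direction hits per TF
    seed: int = 0

    def __post_init__(self) -> None:
        classes = dict(self.tfs)
        if len(classes) != len(self.tfs):
            raise InputError("duplicate TF ids in planted network")
        for tf, cls in self.tfs:
            if cls not in CLASS_GENE_DIR:
                raise InputError(f"{tf}: unknown planted class {cls!r}")
        for reg, tgt in self.edges:
            if reg not in classes or tgt not in classes:
                raise InputError(f"edge ({reg},{tgt}) references unknown TF")
            pair = (classes[reg], classes[tgt])
            if pair not in MEANINGFUL_PAIRS:
                raise InputError(f"planted edge ({reg},{tgt}) has non-meaningful pair {pair}")
        if self.peak_width >= self.upstream_len:
            raise InputError("peak_width must be smaller than upstream_len")
        if self.gene_spacing < 3 * self.upstream_len:
            raise InputError("gene_spacing must be >= 3x upstream_len")


@dataclass
class FixturePaths:
    annotation: Path
    manifest: Path
    deg_csv: Path
    ground_truth: Path
    bed_dir: Path


def _layout_genes(spec: PlantedNetwork) -> dict[str, tuple[str, int, str]]:
    """Place every gene on chr1: gene -> (chrom, tss, strand), alternating strands."""
    names = [tf for tf, _ in spec.tfs]
    names += [f"G_UP{i:03d}" for i in range(1, spec.n_up + 1)]
    names += [f"G_DN{i:03d}" for i in range(1, spec.n_down + 1)]
    names += [f"G_NE{i:03d}" for i in range(1, spec.n_neutral + 1)]
    layout = {}
    for i, name in enumerate(names):
        tss = 2 * spec.upstream_len + i * spec.gene_spacing
        strand = "+" if i % 2 == 0 else "-"
        layout[name] = ("chr1", tss, strand)
    return layout


def _promoter_interval(tss: int, strand: str, upstream_len: int) -> tuple[int, int]:
    if strand == "+":
        return max(0, tss - upstream_len), tss
    return tss + 1, tss + 1 + upstream_len


def _directions(spec: PlantedNetwork) -> dict[str, str]:
    d = {tf: CLASS_GENE_DIR[cls] for tf, cls in spec.tfs}
    d.update({f"G_UP{i:03d}": "up" for i in range(1, spec.n_up + 1)})
    d.update({f"G_DN{i:03d}": "down" for i in range(1, spec.n_down + 1)})
    d.update({f"G_NE{i:03d}": "none" for i in range(1, spec.n_neutral + 1)})
    return d


def _min_salt(
    n_universe: int,
    n_deg: int,
    a_edges: int,
    k_extra: int,
    p_target: float,
    max_salt: int,
) -> int:
    """Smallest salt s with P(X >= a_edges + s) <= p_target.

    X ~ Hypergeom(N=n_universe, K=a_edges+s+k_extra, n=n_deg); the exact
    tail is evaluated, not approximated.
    """
    for s in range(0, max_salt + 1):
        a = a_edges + s
        k = a + k_extra
        if a > n_deg or k > n_universe:
            break
        p = float(hypergeom.sf(a - 1, n_universe, k, n_deg))
        if p <= p_target:
            return s
    raise InputError(
        f"infeasible spec: cannot reach p <= {p_target:.3g} with <= {max_salt} "
        f"salted genes (universe {n_universe}, {n_deg} DEGs in direction); "
        "enlarge the background gene counts"
    )


def _expected_tiers(
    classes: dict[str, str], edges: Sequence[tuple[str, str]]
) -> dict[str, int]:
    # independent re-statement of the tier rule, applied to the planted edges
    da = {tf for tf, c in classes.items() if c == "DA"}
    core = [(u, v) for u, v in edges if u in da and v in da]
    nodes = {n for e in core for n in e}
    indeg = {n: {u for u, v in core if v == n and u != n} for n in nodes}
    t1 = {n for n in nodes if not indeg[n]}
    t2 = {n for n in nodes - t1 if indeg[n] & t1}
    out = {}
    for n in nodes:
        out[n] = 1 if n in t1 else (2 if n in t2 else 3)
    return out


def generate_fixture(spec: PlantedNetwork, out_dir: str | Path) -> FixturePaths:
    """Write annotation TSV, per-TF peak BEDs + manifest, DEG CSV and truth JSON.

    Fully deterministic given the spec (including its seed): identical specs
    produce byte-identical files. Raises on infeasible enrichment demands,
    naming the minimal universe required.
    """
    out_dir = Path(out_dir)
    bed_dir = out_dir / "peaks"
    bed_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    classes = dict(spec.tfs)
    layout = _layout_genes(spec)
    directions = _directions(spec)
    deg_by_dir = {
        d: sorted(g for g, gd in directions.items() if gd == d) for d in ("up", "down")
    }
    n_universe = len(layout)
    n_tests = 2 * len(spec.tfs)  # one peak set per TF x two directions
    p_target = spec.alpha / (n_tests * spec.salt_safety)

    edge_targets = {tf: sorted({t for r, t in spec.edges if r == tf}) for tf in classes}

    # --- decide bound-gene sets per TF ------------------------------------
    bound: dict[str, list[str]] = {}
    for tf in sorted(classes):
        cls = classes[tf]
        targets = list(edge_targets[tf])
        bound_set = list(targets)
        # spurious wrong-direction hits (calibrated sub-threshold noise)
        spurious: list[str] = []
        if spec.noise_promoter_hits and cls in ("DA", "US", "UA", "DS", "NTR"):
            enrich_dirs = set(CLASS_ENRICH_DIRS[cls])
            wrong = "up" if "down" in enrich_dirs and "up" not in enrich_dirs else "down"
            pool = [g for g in deg_by_dir[wrong] if g.startswith("G_")]
            spurious = sorted(
                str(g)
                for g in rng.choice(
                    pool, size=min(spec.noise_promoter_hits, len(pool)), replace=False
                )
            )
            bound_set += spurious
        # salted same-direction DEG promoters to guarantee enrichment
        for d in CLASS_ENRICH_DIRS[cls]:
            a_exist = sum(1 for g in bound_set if directions.get(g) == d)
            k_extra = len(bound_set) - a_exist
            n_deg = len(deg_by_dir[d])
            pool = [g for g in deg_by_dir[d] if g.startswith("G_") and g not in bound_set]
            salt_n = _min_salt(n_universe, n_deg, a_exist, k_extra, p_target, len(pool))
            salted = sorted(
                str(g) for g in rng.choice(pool, size=salt_n, replace=False)
            )
            bound_set += salted
        bound[tf] = sorted(set(bound_set))

    # --- verify every test with the enrichment module's own machinery -----
    from tfrn.enrichment import ContingencyTable, fisher_pvalue

    for tf in sorted(classes):
        cls = classes[tf]
        for d in ("up", "down"):
            deg = set(deg_by_dir[d])
            a = len(deg & set(bound[tf]))
            b = len(deg) - a
            c = len(bound[tf]) - a
            dd = n_universe - a - b - c
            p = fisher_pvalue(ContingencyTable(a, b, c, dd))
            planted = d in CLASS_ENRICH_DIRS[cls]
            if planted and p * n_tests > spec.alpha:
                raise InputError(
                    f"planted enrichment failed verification: {tf}/{d} p={p:.3g}"
                )
            if not planted and p <= spec.alpha:
                raise InputError(
                    f"spurious enrichment in fixture: {tf}/{d} p={p:.3g}; "
                    "lower noise_promoter_hits"
                )

    # --- realize peaks -----------------------------------------------------
    promoters = {
        g: _promoter_interval(tss, strand, spec.upstream_len)
        for g, (_, tss, strand) in layout.items()
    }
    chrom_len = 2 * spec.upstream_len + len(layout) * spec.gene_spacing

    # allowed starts for intergenic noise: gaps between padded promoters
    forbidden = sorted(
        (s - spec.peak_width, e) for s, e in promoters.values()
    )
    gaps: list[tuple[int, int]] = []
    cur = 0
    for s, e in forbidden:
        if s > cur:
            gaps.append((cur, s))
        cur = max(cur, e)
    if cur < chrom_len - spec.peak_width:
        gaps.append((cur, chrom_len - spec.peak_width))

    manifest_rows = []
    for tf in sorted(classes):
        rows = []
        for g in bound[tf]:
            ps, pe = promoters[g]
            off = int(rng.integers(0, (pe - ps) - spec.peak_width + 1))
            rows.append((ps + off, ps + off + spec.peak_width))
        for _ in range(spec.noise_intergenic):
            gi = int(rng.integers(0, len(gaps)))
            gs, ge = gaps[gi]
            start = int(rng.integers(gs, ge - spec.peak_width + 1))
            rows.append((start, start + spec.peak_width))
        bed_path = bed_dir / f"{tf}_{spec.library_label}.bed"
        with open(bed_path, "w") as fh:
            for s, e in sorted(rows):
                fh.write(f"chr1\t{s}\t{e}\n")
        manifest_rows.append((f"peaks/{bed_path.name}", tf, spec.library_label))

    # --- write annotation, manifest, DEGs, ground truth --------------------
    annotation = out_dir / "annotation.tsv"
    with open(annotation, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in sorted(layout):
            chrom, tss, strand = layout[g]
            fh.write(f"{g}\t{chrom}\t{tss}\t{strand}\n")

    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("path\ttf_gene_id\tlibrary_label\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")

    deg_csv = out_dir / "degs.csv"
    with open(deg_csv, "w") as fh:
        fh.write("gene_id,direction\n")
        for d in ("up", "down"):
            for g in deg_by_dir[d]:
                fh.write(f"{g},{d}\n")

    truth = {
        "classes": {tf: classes[tf] for tf in sorted(classes)},
        "network_classes": {
            tf: c for tf, c in sorted(classes.items()) if c in ("DA", "DS", "US", "UA")
        },
        "edges": sorted(map(list, spec.edges)),
        "expected_tiers": _expected_tiers(classes, spec.edges),
        "library_label": spec.library_label,
        "alpha": spec.alpha,
        "upstream_len": spec.upstream_len,
        "seed": spec.seed,
    }
    ground_truth = out_dir / "ground_truth.json"
    with open(ground_truth, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    logger.info(
        "fixture: %d genes, %d TFs, %d planted edges -> %s",
        n_universe, len(spec.tfs), len(spec.edges), out_dir,
    )
    return FixturePaths(annotation, manifest, deg_csv, ground_truth, bed_dir)


def generate_fc_strata(
    spec: PlantedNetwork,
    strata: Sequence[tuple[tuple[float, float], set[str]]],
    out_path: str | Path,
    seed: Optional[int] = None,
) -> Path:
    """Write a DEG CSV with |log2fc| drawn per stratum, sign by direction.

    ``strata`` is a list of ((lo, hi), gene_set); every DEG must fall in
    exactly one stratum — overlaps and uncovered DEGs are errors.
    """
    directions = _directions(spec)
    degs = sorted(g for g, d in directions.items() if d in ("up", "down"))
    assignment: dict[str, tuple[float, float]] = {}
    for (lo, hi), genes in strata:
        if lo < 0 or hi < lo:
            raise InputError(f"invalid |log2fc| range ({lo}, {hi})")
        for g in genes:
            if g in assignment:
                raise InputError(f"gene {g} assigned to overlapping strata")
            assignment[g] = (lo, hi)
    uncovered = [g for g in degs if g not in assignment]
    if uncovered:
        raise InputError(
            "strata do not cover all DEGs; missing e.g. " + ", ".join(uncovered[:5])
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("gene_id,direction,log2fc\n")
        for g in degs:
            lo, hi = assignment[g]
            mag = float(rng.uniform(lo, hi))
            fc = mag if directions[g] == "up" else -mag
            fh.write(f"{g},{directions[g]},{fc:.4f}\n")
    return out_path


def default_fixture(seed: int = 0, **overrides) -> PlantedNetwork:
    """The default 10-TF planted network used throughout the test suite.

    Ten TFs covering all seven classes that can arise: four DAs forming a
    three-tier core (DA1 tier 1 with a self-loop, DA2/DA4 tier 2, DA3
    tier 3), one DS, two USes, two UAs and one NTR decoy; ten planted edges
    spanning all four subnetwork edge kinds. Scale: 1 chromosome, 200
    genes, FDR level 0.001.
    """
    tfs = [
        ("TF_DA1", "DA"), ("TF_DA2", "DA"), ("TF_DA3", "DA"), ("TF_DA4", "DA"),
        ("TF_DS1", "DS"),
        ("TF_US1", "US"), ("TF_US2", "US"),
        ("TF_UA1", "UA"), ("TF_UA2", "UA"),
        ("TF_NTR1", "NTR"),
    ]
    edges = [
        ("TF_DA1", "TF_DA1"),  # self-activation, excluded from tier in-degree
        ("TF_DA1", "TF_DA2"),
        ("TF_DA1", "TF_DA4"),
        ("TF_DA2", "TF_DA3"),
        ("TF_DA1", "TF_DS1"),
        ("TF_US1", "TF_DA2"),
        ("TF_US2", "TF_DS1"),
        ("TF_UA1", "TF_UA2"),
        ("TF_UA1", "TF_US1"),
        ("TF_DS1", "TF_UA1"),
    ]
    params = dict(tfs=tfs, edges=edges, seed=seed)
    params.update(overrides)
    return PlantedNetwork(**params)


def two_strata_for(spec: PlantedNetwork, core_tfs: set[str],
                   bound_genes: dict[str, list[str]],
                   high: tuple[float, float] = (2.0, 4.0),
                   low: tuple[float, float] = (1.0, 2.0)):
    """Build a two-strata assignment: the core TFs' coding genes and the
    background DEGs their peaks bind get the high |log2fc| range; all other
    DEGs (including every peripheral TF's coding gene) get the low range, so
    raising the DEG-calling threshold to the high range's floor removes the
    peripheral TFs from the network by construction."""
    directions = _directions(spec)
    degs = {g for g, d in directions.items() if d in ("up", "down")}
    high_genes = set(core_tfs) & degs
    for tf in core_tfs:
        high_genes |= {
            g for g in bound_genes.get(tf, []) if g in degs and g.startswith("G_")
        }
    low_genes = degs - high_genes
    return [(high, high_genes), (low, low_genes)]


def fixture_bound_genes(spec: PlantedNetwork, fixture: FixturePaths) -> dict[str, list[str]]:
    """Recover, from the written fixture, which genes each TF's peaks bind."""
    from tfrn.enrichment import genes_bound
    from tfrn.genomic_io import extract_promoters, load_peak_manifest, load_tss_annotation

    tss = load_tss_annotation(fixture.annotation, format="tsv")
    promoters = extract_promoters(tss, upstream_len=spec.upstream_len)
    out = {}
    for ps in load_peak_manifest(fixture.manifest):
        out[ps.tf_gene_id] = sorted(genes_bound(promoters, ps))
    return out
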