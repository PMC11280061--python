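"""Readers for annotations, peaks and DEG lists, and promoter derivation.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open ``[start, end)`` internally — BED's
native convention. GFF3 (1-based, closed) is converted on read. The TSS of a
gene is the 0-based position of its first transcribed base.

The promoter of a gene is the fixed-length window immediately 5' of its TSS
(default 1000 bp):

* ``+`` strand: ``[max(0, tss - upstream_len), tss)`` — the TSS base itself
  is excluded.
* ``-`` strand: ``[tss + 1, tss + 1 + upstream_len)`` — the 1000 bp on the
  genomic right of the TSS, optionally clipped to the chromosome end.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class InputError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True, order=True)
class TSSRecord:
    """Strand-aware transcription start site of one gene.

    ``tss`` is the 0-based genomic position of the first transcribed base.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise InputError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in STRANDS:
            raise InputError(f"{self.gene_id}: invalid strand {self.strand!r}")


@dataclass(frozen=True, order=True)
class PromoterRegion:
    """Half-open 5' regulatory window of one gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"{self.gene_id}: invalid promoter [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class PeakInterval:
    """One binding peak, half-open per BED."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"invalid peak [{self.start}, {self.end})")


@dataclass
class PeakSet:
    """All binding peaks of one TF under one peak-calling library label."""

    tf_gene_id: str
    library_label: str
    peaks: list[PeakInterval] = field(default_factory=list)
    name: Optional[str] = None  # distinguishes multiple sets per TF

    def __post_init__(self) -> None:
        if not self.tf_gene_id:
            raise InputError("PeakSet requires a nonempty tf_gene_id")
        self.peaks = sorted(set(self.peaks), key=lambda p: (p.chrom, p.start, p.end))
        if self.name is None:
            self.name = f"{self.tf_gene_id}_{self.library_label}"


@dataclass
class DEGTable:
    """Differentially expressed genes with direction and optional log2FC.

    Wraps a DataFrame with columns gene_id, direction ({up, down}) and
    optionally log2fc / adj_p. No gene may carry both directions.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "direction"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"DEG table missing columns: {sorted(missing)}")
        bad_dir = set(self.frame["direction"]) - {"up", "down"}
        if bad_dir:
            raise InputError(f"invalid DEG directions: {sorted(bad_dir)}")
        dup = self.frame.groupby("gene_id")["direction"].nunique()
        both = sorted(dup[dup > 1].index)
        if both:
            raise InputError(
                f"genes present in both up and down lists: {', '.join(both)}"
            )
        self.frame = (
            self.frame.drop_duplicates(subset=["gene_id", "direction"])
            .sort_values("gene_id")
            .reset_index(drop=True)
        )
        if "log2fc" in self.frame.columns:
            fc = self.frame.dropna(subset=["log2fc"])
            wrong = fc[
                ((fc["direction"] == "up") & (fc["log2fc"] < 0))
                | ((fc["direction"] == "down") & (fc["log2fc"] > 0))
            ]
            if len(wrong):
                raise InputError(
                    "log2fc sign inconsistent with direction for: "
                    + ", ".join(sorted(wrong["gene_id"]))
                )

    def genes(self, direction: str) -> set[str]:
        sel = self.frame[self.frame["direction"] == direction]
        return set(sel["gene_id"])

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    @property
    def down(self) -> set[str]:
        return self.genes("down")

    def direction_of(self, gene_id: str) -> str:
        """Return up/down/none for a gene."""
        if gene_id in self.up:
            return "up"
        if gene_id in self.down:
            return "down"
        return "none"

    def filter_by_fc(self, threshold: float) -> "DEGTable":
        """Re-call DEGs at a stricter |log2fc| threshold."""
        if "log2fc" not in self.frame.columns:
            raise InputError("DEG table lacks log2fc; cannot filter")
        if self.frame["log2fc"].isna().any():
            missing = self.frame[self.frame["log2fc"].isna()]["gene_id"]
            raise InputError(
                "log2fc missing for: " + ", ".join(sorted(missing))
            )
        kept = self.frame[self.frame["log2fc"].abs() >= threshold]
        return DEGTable(kept.reset_index(drop=True))


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_tss_annotation(
    path: str | Path,
    format: str = "tsv",
    tss_rule: str = "most-upstream",
) -> list[TSSRecord]:
    """Load one TSS per gene from a GFF3 or a 4-column TSV.

    TSV dialect: ``gene_id  chrom  tss  strand`` with ``tss`` already a
    0-based position (header optional). GFF3: ``gene`` features anchor the
    record; when ``mRNA`` children are present the representative TSS among
    isoforms follows ``tss_rule``:

    * ``most-upstream`` (default): the transcription start that maximizes
      promoter coverage (smallest start on ``+``, largest end on ``-``).
    * ``first-listed``: the first transcript encountered in the file.

    Returns records sorted by gene_id; duplicate gene ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation file not found: {path}")
    if format not in ("tsv", "gff3"):
        raise InputError(f"unknown annotation format: {format}")
    if tss_rule not in ("most-upstream", "first-listed"):
        raise InputError(f"unknown tss_rule: {tss_rule}")

    records: dict[str, TSSRecord] = {}
    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 4:
                    raise InputError(f"{path}:{lineno}: expected 4 columns")
                gene_id, chrom, tss_s, strand = parts[:4]
                if lineno == 1 and gene_id.lower() in ("gene_id", "gene"):
                    continue  # header
                try:
                    tss = int(tss_s)
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: non-integer TSS {tss_s!r}"
                    ) from None
                if strand not in STRANDS:
                    raise InputError(
                        f"{path}:{lineno}: gene {gene_id} lacks a valid strand"
                    )
                if gene_id in records:
                    raise InputError(f"{path}:{lineno}: duplicate gene {gene_id}")
                records[gene_id] = TSSRecord(gene_id, chrom, tss, strand)
    else:
        # genes anchor coordinates; mRNA children refine the isoform TSS
        genes: dict[str, tuple[str, int, int, str]] = {}
        transcripts: dict[str, list[tuple[int, int]]] = {}
        first_tx: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise InputError(
                        f"{path}:{lineno}: malformed GFF3 line "
                        f"({len(parts)} columns)"
                    )
                chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr = parts
                if ftype not in ("gene", "mRNA", "transcript"):
                    continue
                try:
                    start1, end1 = int(start_s), int(end_s)
                except ValueError:
                    raise InputError(
                        f"{path}:{lineno}: non-integer coordinates"
                    ) from None
                attrs = _parse_gff3_attributes(attr)
                # GFF3 1-based closed -> 0-based half-open
                start0, end0 = start1 - 1, end1
                if ftype == "gene":
                    gid = attrs.get("ID")
                    if not gid:
                        raise InputError(f"{path}:{lineno}: gene without ID")
                    if strand not in STRANDS:
                        raise InputError(
                            f"{path}:{lineno}: gene {gid} lacks a valid strand"
                        )
                    genes[gid] = (chrom, start0, end0, strand)
                else:
                    parent = attrs.get("Parent")
                    if parent:
                        transcripts.setdefault(parent, []).append((start0, end0))
                        first_tx.setdefault(parent, (start0, end0))
        for gid, (chrom, gstart, gend, strand) in genes.items():
            txs = transcripts.get(gid)
            if txs:
                if tss_rule == "first-listed":
                    s, e = first_tx[gid]
                else:
                    s = min(t[0] for t in txs)
                    e = max(t[1] for t in txs)
            else:
                s, e = gstart, gend
            tss = s if strand == "+" else e - 1
            records[gid] = TSSRecord(gid, chrom, tss, strand)

    return sorted(records.values(), key=lambda r: r.gene_id)


def extract_promoters(
    tss_records: Sequence[TSSRecord],
    upstream_len: int = 1000,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[PromoterRegion]:
    """Derive the fixed-length 5' window upstream of each TSS.

    Genes whose promoter clips to an empty interval (``+`` strand TSS at
    position 0, or ``-`` strand TSS at the chromosome end) are dropped with
    a warning; callers needing the exclusion list can diff the gene ids.
    """
    if upstream_len <= 0:
        raise InputError("upstream_len must be positive")
    out: list[PromoterRegion] = []
    dropped: list[str] = []
    for rec in tss_records:
        if rec.strand == "+":
            start = max(0, rec.tss - upstream_len)
            end = rec.tss
        else:
            start = rec.tss + 1
            end = start + upstream_len
            if chrom_sizes is not None:
                if rec.chrom not in chrom_sizes:
                    raise InputError(
                        f"{rec.gene_id}: chromosome {rec.chrom!r} not in chrom_sizes"
                    )
                end = min(end, chrom_sizes[rec.chrom])
        if start >= end:
            dropped.append(rec.gene_id)
            continue
        out.append(PromoterRegion(rec.gene_id, rec.chrom, start, end, rec.strand))
    if dropped:
        logger.warning(
            "%d genes dropped: promoter clipped to empty (%s%s)",
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    return out


def load_peak_bed(
    path: str | Path,
    tf_gene_id: str,
    library_label: str,
    name: Optional[str] = None,
) -> PeakSet:
    """Read a BED3+ file into one TF's peak set.

    Records with ``start >= end`` are dropped with a warning tally. Peaks are
    deduplicated and sorted; an empty BED yields an empty (valid) PeakSet.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED file not found: {path}")
    peaks: list[PeakInterval] = []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                n_dropped += 1
                continue
            score = None
            if len(parts) >= 5:
                try:
                    score = float(parts[4])
                except ValueError:
                    score = None
            peaks.append(PeakInterval(chrom, start, end, score))
    if n_dropped:
        logger.warning("%s: dropped %d zero/negative-length peaks", path, n_dropped)
    return PeakSet(tf_gene_id, library_label, peaks, name=name)


def load_peak_manifest(path: str | Path) -> list[PeakSet]:
    """Load all peak sets listed in a manifest TSV.

    Columns: ``path  tf_gene_id  library_label`` (header optional). Relative
    BED paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest not found: {path}")
    sets: list[PeakSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: manifest needs 3 columns")
            bed, tf, lib = parts[:3]
            if lineno == 1 and bed.lower() == "path":
                continue
            bed_path = Path(bed)
            if not bed_path.is_absolute():
                bed_path = path.parent / bed_path
            sets.append(
                load_peak_bed(bed_path, tf, lib, name=f"{bed_path.stem}")
            )
    return sets


def load_deg_lists(
    up_path: Optional[str | Path] = None,
    down_path: Optional[str | Path] = None,
    combined_path: Optional[str | Path] = None,
) -> DEGTable:
    """Load DEGs from two one-column lists or one combined CSV.

    The combined CSV needs columns gene_id and direction; log2fc and adj_p
    are carried through when present. A gene appearing in both directions is
    a hard error naming the offenders.
    """
    if combined_path is not None:
        frame = pd.read_csv(combined_path)
        return DEGTable(frame)
    if up_path is None or down_path is None:
        raise InputError("need either combined_path or both up_path and down_path")
    rows = []
    for p, direction in ((up_path, "up"), (down_path, "down")):
        with open(p) as fh:
            for line in fh:
                gid = line.strip().split(",")[0].split("\t")[0]
                if gid and not gid.startswith("#") and gid.lower() != "gene_id":
                    rows.append({"gene_id": gid, "direction": direction})
    return DEGTable(pd.DataFrame(rows, columns=["gene_id", "direction"]))


def write_promoters_bed(promoters: Iterable[PromoterRegion], path: str | Path) -> None:
    """Write promoters as BED6 (name = gene_id)."""
    with open(path, "w") as fh:
        for p in sorted(promoters, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n")


def write_tss_tsv(records: Iterable[TSSRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "chrom", "tss", "strand"])
        for r in sorted(records, key=lambda x: x.gene_id):
            w.writerow([r.gene_id, r.chrom, r.tss, r.strand])
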