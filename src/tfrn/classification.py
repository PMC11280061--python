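"""TF classification from enrichment directions and own-gene regulation (step 2).

A TF whose peaks are enriched in DEG promoters is classified by crossing its
enrichment pattern (up only / down only / both) with the differential
expression of its own coding gene (up / down / not a DEG):

================  ========  =====
enrichment        gene      class
================  ========  =====
uDEG promoters    uDEG      UA  (upregulated activator)
uDEG promoters    dDEG      DS  (downregulated suppressor)
dDEG promoters    uDEG      US  (upregulated suppressor)
dDEG promoters    dDEG      DA  (downregulated activator)
both              uDEG      UR
both              dDEG      DR
any               not DEG   NTR (non-transcriptionally regulated)
================  ========  =====

Only the four classes DA, DS, US, UA carry an interpretable sign and enter
network construction; DR/UR/NTR cannot be univocally characterized as
activators or suppressors and are filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from tfrn.enrichment import EnrichmentRecord
from tfrn.genomic_io import DEGTable, InputError

logger = logging.getLogger(__name__)

ALL_CLASSES = ("DA", "DS", "US", "UA", "DR", "UR", "NTR")
NETWORK_CLASSES = ("DA", "DS", "US", "UA")


@dataclass(frozen=True)
class TFClassification:
    tf_gene_id: str
    tf_class: str
    enriched_up: bool
    enriched_down: bool
    gene_direction: str  # up / down / none


def classify_tf(enriched_up: bool, enriched_down: bool, gene_direction: str) -> str:
    """Deterministic class for one (enrichment pattern, gene direction) cell."""
    if not (enriched_up or enriched_down):
        raise InputError("classify_tf requires at least one enrichment direction")
    if gene_direction not in ("up", "down", "none"):
        raise InputError(f"invalid gene_direction: {gene_direction!r}")
    if gene_direction == "none":
        return "NTR"
    if enriched_up and enriched_down:
        return "UR" if gene_direction == "up" else "DR"
    if enriched_up:  # enriched in uDEG promoters only
        return "UA" if gene_direction == "up" else "DS"
    # enriched in dDEG promoters only
    return "US" if gene_direction == "up" else "DA"


def classify_all(
    records: Sequence[EnrichmentRecord],
    deg_table: DEGTable,
) -> list[TFClassification]:
    """Classify every TF with at least one enriched record.

    Enrichment flags are aggregated across a TF's peak sets before
    classification: the TF is enriched in a direction if ANY of its peak
    sets is. A TF with one set enriched up and another down therefore takes
    the DR/UR/NTR path.
    """
    up_flags: dict[str, bool] = {}
    down_flags: dict[str, bool] = {}
    for rec in records:
        if not rec.enriched:
            continue
        if rec.deg_direction == "up":
            up_flags[rec.tf_gene_id] = True
        else:
            down_flags[rec.tf_gene_id] = True
        up_flags.setdefault(rec.tf_gene_id, False)
        down_flags.setdefault(rec.tf_gene_id, False)

    out = []
    for tf in sorted(up_flags):
        e_up, e_down = up_flags[tf], down_flags[tf]
        gene_dir = deg_table.direction_of(tf)
        out.append(
            TFClassification(tf, classify_tf(e_up, e_down, gene_dir), e_up, e_down, gene_dir)
        )
    logger.info(
        "classification: %d enriched TFs -> %s",
        len(out),
        {c: sum(1 for t in out if t.tf_class == c) for c in ALL_CLASSES},
    )
    return out


def retain_network_classes(
    classifications: Iterable[TFClassification],
) -> list[TFClassification]:
    """Keep only DA/DS/US/UA; DR, UR and NTR are logged and removed."""
    kept, removed = [], []
    for c in classifications:
        (kept if c.tf_class in NETWORK_CLASSES else removed).append(c)
    if removed:
        logger.info(
            "filtered %d TFs outside the four network classes: %s",
            len(removed),
            ", ".join(f"{c.tf_gene_id}({c.tf_class})" for c in removed),
        )
    return kept


def classifications_to_frame(classifications: Sequence[TFClassification]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "tf_gene_id": c.tf_gene_id,
                "class": c.tf_class,
                "enriched_up": c.enriched_up,
                "enriched_down": c.enriched_down,
                "gene_direction": c.gene_direction,
            }
            for c in classifications
        ]
    )
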