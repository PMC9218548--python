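"""Set-overlap summaries: DEG/DSG Venn parts and eyespot cross-tabulation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


@dataclass
class GeneList:
    """A named gene list, optionally with per-gene direction labels
    (e.g. up- vs down-regulated in eyespot tissue)."""

    name: str
    members: set
    directions: dict | None = None  # gene -> "up" | "down"

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if self.directions is not None:
            extra = set(self.directions) - self.members
            if extra:
                raise ValueError(f"direction labels for non-members: {sorted(extra)}")
            if set(self.directions) != self.members:
                raise ValueError("direction labels must cover the whole list")
            bad = set(self.directions.values()) - {"up", "down"}
            if bad:
                raise ValueError(f"unknown direction labels: {sorted(bad)}")

    def subset(self, direction: str) -> set:
        if self.directions is None:
            raise ValueError("list has no direction labels")
        return {g for g, d in self.directions.items() if d == direction}


def overlap_counts(set_a, set_b) -> tuple[int, int, int]:
    """Venn parts (|A only|, |B only|, |A and B|)."""
    a, b = set(set_a), set(set_b)
    return len(a - b), len(b - a), len(a & b)


def eyespot_crosstab(eyespot: GeneList, de_results: dict, padj: float = 0.05) -> dict:
    """Per-stage 2x2 counts of eyespot-direction vs seasonal-form direction.

    WS-up means padj < threshold and log2FC > 0; DS-up means padj < threshold
    and log2FC < 0. Listed genes absent from the DE results count as not-DE.
    """
    up = eyespot.subset("up")
    down = eyespot.subset("down")
    out = {}
    for stage, results in de_results.items():
        table = {r.feature: r for r in results}
        missing = eyespot.members - set(table)
        if missing:
            logger.info(
                "stage %s: %d eyespot genes absent from DE results", stage, len(missing)
            )
        ws_up = {f for f, r in table.items() if r.padj < padj and r.log2fc > 0}
        ds_up = {f for f, r in table.items() if r.padj < padj and r.log2fc < 0}
        out[stage] = {
            "eyespot_up_ws_up": len(up & ws_up),
            "eyespot_up_ds_up": len(up & ds_up),
            "eyespot_down_ws_up": len(down & ws_up),
            "eyespot_down_ds_up": len(down & ds_up),
        }
    return out


def overlap_fraction_de_ds(de_genes, ds_genes) -> float:
    """|DE and DS| / |DE or DS| among the restricted sets; 0 for empty union."""
    de, ds = set(de_genes), set(ds_genes)
    union = de | ds
    return len(de & ds) / len(union) if union else 0.0
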