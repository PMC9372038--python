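"""Translate MQTL genetic (cM) intervals into physical (bp) intervals.

The CI endpoints are anchored by the nearest consensus-map markers at or
outside the genetic CI that have a known physical position; the MQTL peak in
bp is then estimated from the cM-to-bp scale of the interval:

    peak_bp = start_bp + (end_bp - start_bp) / (end_cm - start_cm) * ci95 / 2

clamped into [start_bp, end_bp]; a zero-width genetic interval degenerates to
the bp midpoint. Coordinates are 1-based inclusive internally; BED export is
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .consensus_map import ConsensusMap
from .meta_analysis import MQTL


@dataclass
class MarkerPhysicalTable:
    """marker -> (chromosome, bp), e.g. from prior BLASTN of marker sequences."""

    table: pd.DataFrame  # columns: marker, chromosome, bp

    def __post_init__(self):
        df = pd.DataFrame(self.table, columns=["marker", "chromosome", "bp"]).copy()
        df["bp"] = df["bp"].astype(int)
        if (df["bp"] < 1).any():
            raise ValueError("physical positions are 1-based; bp must be >= 1")
        self.table = df.drop_duplicates(subset="marker", keep="first").reset_index(drop=True)
        self._index = {
            m: (c, int(b)) for m, c, b in zip(df["marker"], df["chromosome"], df["bp"])
        }

    @classmethod
    def from_tsv(cls, path) -> "MarkerPhysicalTable":
        return cls(pd.read_csv(path, sep="\t"))

    def get(self, marker: str):
        return self._index.get(marker)


@dataclass(frozen=True)
class PhysicalInterval:
    chromosome: str
    start_bp: int
    end_bp: int
    peak_bp: int
    flags: tuple = ()

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")
        if not (self.start_bp <= self.peak_bp <= self.end_bp):
            raise ValueError("peak outside interval")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def peak_position_bp(
    start_bp: int, end_bp: int, start_cm: float, end_cm: float, ci95_cm: float
) -> int:
    """MQTL peak position in bp (see module docstring for the formula)."""
    if end_cm == start_cm:
        return int(round((start_bp + end_bp) / 2.0))
    peak = start_bp + (end_bp - start_bp) / (end_cm - start_cm) * ci95_cm / 2.0
    return int(round(min(max(peak, start_bp), end_bp)))


class Unanchored(Exception):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def anchor_mqtl(
    mqtl: MQTL, cmap: ConsensusMap, phys: MarkerPhysicalTable
) -> PhysicalInterval:
    """Physical interval for one MQTL, or raise :class:`Unanchored`.

    Flank markers are the nearest consensus markers at/outside each genetic
    CI endpoint that resolve to a physical position on the same chromosome.
    When no marker lies at/outside an endpoint, the nearest resolvable marker
    inside is used and the side is flagged ``extended_left``/``extended_right``.
    """
    cpos = cmap.positions(mqtl.chromosome)
    cands = []
    for marker, cm in cpos.items():
        hit = phys.get(marker)
        if hit is None:
            continue
        chrom_p, bp = hit
        if chrom_p != mqtl.chromosome:
            continue  # physically mapped elsewhere: unusable for this MQTL
        cands.append((marker, cm, bp))
    if not cands:
        raise Unanchored("no_physical_markers")
    flags: list[str] = []
    left = [c for c in cands if c[1] <= mqtl.ci_start_cm]
    right = [c for c in cands if c[1] >= mqtl.ci_end_cm]
    if left:
        lmk = max(left, key=lambda c: c[1])
    else:
        lmk = min(cands, key=lambda c: c[1])
        flags.append("extended_left")
    if right:
        rmk = min(right, key=lambda c: c[1])
    else:
        rmk = max(cands, key=lambda c: c[1])
        flags.append("extended_right")
    start_bp, end_bp = lmk[2], rmk[2]
    start_cm, end_cm = lmk[1], rmk[1]
    if start_bp > end_bp:
        # genetic and physical orders disagree at the flanks
        start_bp, end_bp = end_bp, start_bp
        flags.append("flipped_orientation")
    peak = peak_position_bp(start_bp, end_bp, start_cm, end_cm, mqtl.ci_width_cm)
    return PhysicalInterval(
        chromosome=mqtl.chromosome,
        start_bp=start_bp,
        end_bp=end_bp,
        peak_bp=peak,
        flags=tuple(flags),
    )


def anchor_all(
    mqtls: Sequence[MQTL], cmap: ConsensusMap, phys: MarkerPhysicalTable
) -> tuple[dict, pd.DataFrame]:
    """Anchor a batch; returns ({mqtl name: PhysicalInterval}, unanchored report)."""
    anchored: dict[str, PhysicalInterval] = {}
    misses = []
    for m in mqtls:
        try:
            anchored[m.name] = anchor_mqtl(m, cmap, phys)
        except Unanchored as u:
            misses.append({"name": m.name, "reason": u.reason})
    return anchored, pd.DataFrame(misses, columns=["name", "reason"])


def to_bed(
    mqtls: Sequence[MQTL], anchored: dict, path=None
) -> pd.DataFrame:
    """BED (0-based half-open) of anchored MQTLs; score = mean PVE."""
    rows = []
    for m in mqtls:
        iv = anchored.get(m.name)
        if iv is None:
            continue
        rows.append(
            {
                "chrom": iv.chromosome,
                "chromStart": iv.start_bp - 1,
                "chromEnd": iv.end_bp,
                "name": m.name,
                "score": round(m.mean_pve, 2),
            }
        )
    bed = pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd", "name", "score"])
    if path is not None:
        bed.to_csv(path, sep="\t", header=False, index=False)
    return bed
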