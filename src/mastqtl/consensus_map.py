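"""Linkage maps and consensus-map construction by anchor-interval averaging.

Multiple published linkage maps (plus per-study maps carrying QTL-flanking
markers) are merged per chromosome into one consensus map. The algorithm is a
deterministic anchor-rescale-and-average surrogate for LP-based consensus
builders:

1. the densest map on a chromosome is the *frame* and fixes marker order;
2. markers shared by ≥2 maps are *anchors*; every marker gets a provisional
   coordinate on the frame scale by piecewise-linear rescaling through the
   anchors it shares with the frame (maps sharing <2 anchors are reported
   unplaced, never silently dropped);
3. the consensus gap between consecutive anchors is the weighted mean of that
   gap in every map containing both anchors (weights default to per-map
   marker count on the chromosome);
4. non-anchor markers are placed by fractional interpolation between their
   flanking anchors *in their own source map*; positions are finally shifted
   so each chromosome starts at 0.

Order conflicts between a source map and the frame are resolved in favour of
the frame and flagged in the provenance report.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class GeneticMap:
    """An ordered set of (chromosome, marker, cM) entries."""

    map_id: str
    entries: pd.DataFrame  # columns: chromosome, marker, cm

    def __post_init__(self):
        df = pd.DataFrame(self.entries, columns=["chromosome", "marker", "cm"]).copy()
        df["cm"] = df["cm"].astype(float)
        if (df["cm"] < 0).any():
            raise ValueError(f"map {self.map_id}: negative cM position")
        dup = df.duplicated(subset=["chromosome", "marker"])
        if dup.any():
            raise ValueError(f"map {self.map_id}: duplicate marker within a chromosome")
        self.entries = df.sort_values(["chromosome", "cm", "marker"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_tsv(cls, path, map_id: str | None = None) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        return cls(map_id or str(path), df[["chromosome", "marker", "cm"]])

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.entries["chromosome"].unique())

    def chromosome_frame(self, chromosome: str) -> pd.DataFrame:
        return self.entries[self.entries["chromosome"] == chromosome]

    def position(self, chromosome: str, marker: str) -> float | None:
        sub = self.entries[
            (self.entries["chromosome"] == chromosome) & (self.entries["marker"] == marker)
        ]
        if sub.empty:
            return None
        return float(sub["cm"].iloc[0])

    def positions(self, chromosome: str) -> dict:
        sub = self.chromosome_frame(chromosome)
        return dict(zip(sub["marker"], sub["cm"].astype(float)))


@dataclass
class ConsensusMap:
    """Consensus entries plus per-marker source provenance and reports."""

    entries: pd.DataFrame  # columns: chromosome, marker, cm, sources (;-joined)
    unplaced: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chromosome", "marker", "map_id", "reason"])
    )
    conflicts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chromosome", "marker", "map_id"])
    )
    case_fold: bool = False

    def __post_init__(self):
        self.entries = self.entries.sort_values(
            ["chromosome", "cm", "marker"], kind="stable"
        ).reset_index(drop=True)
        key = self.entries["marker"].str.lower() if self.case_fold else self.entries["marker"]
        self._by_marker = {}
        for c, m, p in zip(self.entries["chromosome"], key, self.entries["cm"]):
            self._by_marker.setdefault(m, (c, float(p)))

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.entries["chromosome"].unique())

    def chromosome_length(self, chromosome: str) -> float:
        sub = self.entries[self.entries["chromosome"] == chromosome]
        return float(sub["cm"].max() - sub["cm"].min()) if len(sub) else 0.0

    def positions(self, chromosome: str) -> dict:
        sub = self.entries[self.entries["chromosome"] == chromosome]
        return dict(zip(sub["marker"], sub["cm"].astype(float)))

    def marker_lookup(self, marker: str):
        """Exact-match lookup -> (chromosome, cM) or None.

        Case-sensitive unless the map was built with ``case_fold=True``.
        """
        key = marker.lower() if self.case_fold else marker
        return self._by_marker.get(key)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def marker_lookup(cmap: ConsensusMap, marker: str):
    return cmap.marker_lookup(marker)


def _interp_with_extrapolation(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp plus linear extrapolation using the edge segments."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        s0 = (fp[1] - fp[0]) / (xp[1] - xp[0]) if xp[1] > xp[0] else 1.0
        s1 = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2]) if xp[-1] > xp[-2] else 1.0
        y[lo] = fp[0] + (x[lo] - xp[0]) * s0
        y[hi] = fp[-1] + (x[hi] - xp[-1]) * s1
    return y


def _merge_chromosome(chromosome, chrom_maps, weights, unplaced, conflicts):
    """Merge one chromosome; returns list of (marker, cm, sources)."""
    # frame = densest map (ties: input order)
    frame = max(chrom_maps, key=lambda m: len(m.chromosome_frame(chromosome)))
    pos = {m.map_id: m.positions(chromosome) for m in chrom_maps}
    membership = defaultdict(list)
    for mid, d in pos.items():
        for mk in d:
            membership[mk].append(mid)

    frame_pos = pos[frame.map_id]
    anchors = {mk for mk, mids in membership.items() if len(mids) >= 2}

    # Provisional frame-scale coordinate for every marker.
    provisional = dict(frame_pos)
    usable_maps = [frame.map_id]
    for m in chrom_maps:
        if m.map_id == frame.map_id:
            continue
        d = pos[m.map_id]
        shared = sorted(
            (mk for mk in d if mk in provisional), key=lambda mk: d[mk]
        )
        # drop order-conflicting shared markers (frame order wins)
        kept = []
        for mk in shared:
            while kept and provisional[kept[-1]] > provisional[mk]:
                conflicts.append(
                    {"chromosome": chromosome, "marker": kept.pop(), "map_id": m.map_id}
                )
            kept.append(mk)
        if len(kept) < 2:
            for mk in d:
                if mk not in provisional:
                    unplaced.append(
                        {
                            "chromosome": chromosome,
                            "marker": mk,
                            "map_id": m.map_id,
                            "reason": "unanchored",
                        }
                    )
            continue
        usable_maps.append(m.map_id)
        xp = np.array([d[mk] for mk in kept])
        fp = np.array([provisional[mk] for mk in kept])
        new = [mk for mk in d if mk not in provisional]
        if new:
            coords = _interp_with_extrapolation(np.array([d[mk] for mk in new]), xp, fp)
            for mk, c in zip(new, coords):
                provisional[mk] = float(c)

    if len(usable_maps) == 1 and len(chrom_maps) == 1:
        # single map: consensus identical up to the final min-shift
        anchors = set(frame_pos)

    # anchors that ended up placeable
    placed_anchors = sorted(
        (mk for mk in anchors if mk in provisional), key=lambda mk: (provisional[mk], mk)
    )
    if not placed_anchors:
        placed_anchors = sorted(provisional, key=lambda mk: (provisional[mk], mk))

    # Consensus anchor coordinates: weighted mean over maps of the anchor's
    # translation-aligned position (each map shifted so its leftmost shared
    # anchor sits at that anchor's provisional frame coordinate). Averaging
    # positions, not gaps, keeps per-map noise from accumulating along the
    # chromosome. Frame order is restored afterwards by re-sorting values.
    shifts = {}
    for mid in usable_maps:
        d = pos[mid]
        own = [a for a in placed_anchors if a in d]
        if not own:
            continue
        a0 = min(own, key=lambda a: d[a])
        shifts[mid] = provisional[a0] - d[a0]
    cons: dict = {}
    for a in placed_anchors:
        vals, ws = [], []
        for mid in usable_maps:
            d = pos[mid]
            if a in d and mid in shifts:
                vals.append(d[a] + shifts[mid])
                ws.append(weights[mid])
        cons[a] = float(np.average(vals, weights=ws)) if vals else provisional[a]
    ordered = sorted(cons.values())
    cons = {a: v for a, v in zip(placed_anchors, ordered)}

    # Non-anchor markers: fractional interpolation within their own map.
    out = {}
    for mk in provisional:
        if mk in cons:
            continue
        mid = membership[mk][0]
        if mid not in usable_maps:
            continue
        d = pos[mid]
        amks = [a for a in placed_anchors if a in d]
        if len(amks) < 2:
            # lone-map marker set with no anchors handled above
            out[mk] = provisional[mk]
            continue
        xp = np.array([d[a] for a in amks])
        fp = np.array([cons[a] for a in amks])
        order = np.argsort(xp, kind="stable")
        out[mk] = float(
            _interp_with_extrapolation(np.array([d[mk]]), xp[order], fp[order])[0]
        )
    out.update(cons)

    shift = min(out.values())
    rows = [
        (mk, p - shift, ";".join(sorted(membership[mk])))
        for mk, p in sorted(out.items(), key=lambda kv: (kv[1], kv[0]))
    ]
    return rows


def build_consensus(
    maps: Sequence[GeneticMap],
    weights: Mapping[str, float] | None = None,
    case_fold: bool = False,
) -> ConsensusMap:
    """Merge linkage maps into a consensus map (see module docstring).

    ``weights`` maps map_id to a positive weight; the default weight of a map
    on a chromosome is its marker count there, so denser maps pull anchor
    spacing harder.
    """
    if not maps:
        raise ValueError("at least one map required")
    unplaced: list[dict] = []
    conflicts: list[dict] = []
    rows = []
    chroms = sorted({c for m in maps for c in m.chromosomes})
    for chromosome in chroms:
        chrom_maps = [m for m in maps if len(m.chromosome_frame(chromosome))]
        if weights is None:
            w = {m.map_id: float(len(m.chromosome_frame(chromosome))) for m in chrom_maps}
        else:
            w = {m.map_id: float(weights[m.map_id]) for m in chrom_maps}
        for mk, p, src in _merge_chromosome(chromosome, chrom_maps, w, unplaced, conflicts):
            rows.append({"chromosome": chromosome, "marker": mk, "cm": p, "sources": src})
    return ConsensusMap(
        entries=pd.DataFrame(rows, columns=["chromosome", "marker", "cm", "sources"]),
        unplaced=pd.DataFrame(unplaced, columns=["chromosome", "marker", "map_id", "reason"]),
        conflicts=pd.DataFrame(conflicts, columns=["chromosome", "marker", "map_id"]),
        case_fold=case_fold,
    )
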