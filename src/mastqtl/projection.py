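"""QTL projection from source linkage maps onto the consensus map.

Each QTL is rescaled through a *projection context*: a pair of markers common
to the source and consensus maps that flank the QTL peak. Among all flanking
common pairs, the pair with the smallest interval-length ratio discrepancy is
chosen, subject to the ratio not exceeding ``max_ratio``; when the nearest
pair fails the search widens outward. The peak and CI endpoints are mapped by
the piecewise-linear transform defined by the common markers. QTLs whose
transformed CI exceeds ``max_ci_cm`` are rejected as large-CI, mirroring the
usual attrition in consensus-map meta-analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .consensus_map import ConsensusMap, GeneticMap, _interp_with_extrapolation
from .qtl_data import QTLRecord


@dataclass(frozen=True)
class ProjectionConfig:
    max_ratio: float = 5.0       # max allowed flanking-interval length ratio
    min_p: float = 0.05          # homogeneity-test threshold
    max_ci_cm: float = 50.0      # reject QTLs with larger projected CI

    def __post_init__(self):
        if self.max_ratio < 1:
            raise ValueError("max_ratio must be >= 1")
        if not (0 < self.min_p < 1):
            raise ValueError("min_p must be in (0, 1)")


@dataclass(frozen=True)
class ProjectionContext:
    """A chosen common-marker pair plus the full common scaffold."""

    left_marker: str
    right_marker: str
    source_left: float
    source_right: float
    consensus_left: float
    consensus_right: float
    # all common markers, sorted by source position, for CI endpoints that
    # fall outside the context interval (dynamic-strategy behaviour)
    scaffold_source: tuple = ()
    scaffold_consensus: tuple = ()

    @property
    def scale(self) -> float:
        return (self.consensus_right - self.consensus_left) / (
            self.source_right - self.source_left
        )


@dataclass(frozen=True)
class ProjectedQTL:
    source: QTLRecord
    consensus_chromosome: str | None = None
    peak_cm: float | None = None
    ci_start_cm: float | None = None
    ci_end_cm: float | None = None
    context: ProjectionContext | None = None
    status: str = "projected"  # or "rejected"
    reason: str | None = None

    @property
    def projected(self) -> bool:
        return self.status == "projected"

    @property
    def ci_width_cm(self) -> float | None:
        if self.ci_start_cm is None or self.ci_end_cm is None:
            return None
        return self.ci_end_cm - self.ci_start_cm


class Rejection(Exception):
    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def homogeneity_p(scale_a: float, scale_b: float) -> float:
    """Heuristic p-value for proportionality of two interval scale factors.

    A unit-variance z statistic on the log of the scale ratio: identical
    scales give p = 1, a tenfold discrepancy p ≈ 0.02. Used as a secondary
    gate (the primary gate is the max_ratio bound on the interval ratio).
    """
    if scale_a <= 0 or scale_b <= 0:
        return 0.0
    z = abs(math.log(scale_a / scale_b))
    return float(2.0 * (1.0 - norm.cdf(z)))


def _common_scaffold(smap_pos: dict, cmap_pos: dict) -> tuple[list, np.ndarray, np.ndarray]:
    common = sorted(set(smap_pos) & set(cmap_pos), key=lambda m: (smap_pos[m], m))
    # drop markers whose consensus order conflicts with source order
    kept: list[str] = []
    for mk in common:
        if kept and cmap_pos[mk] < cmap_pos[kept[-1]]:
            continue
        kept.append(mk)
    xs = np.array([smap_pos[m] for m in kept])
    xc = np.array([cmap_pos[m] for m in kept])
    return kept, xs, xc


def select_projection_context(
    qtl: QTLRecord,
    smap: GeneticMap,
    cmap: ConsensusMap,
    cfg: ProjectionConfig | None = None,
) -> ProjectionContext:
    """Choose the common-marker pair flanking the peak (see module docstring).

    Raises :class:`Rejection` with reason ``no_common_markers``,
    ``peak_out_of_map`` or ``no_feasible_context``.
    """
    cfg = cfg or ProjectionConfig()
    chrom = qtl.chromosome
    spos = smap.positions(chrom)
    if not spos:
        raise Rejection("no_common_markers")
    if qtl.peak_cm is None:
        raise Rejection("missing_peak")
    if not (min(spos.values()) <= qtl.peak_cm <= max(spos.values())):
        raise Rejection("peak_out_of_map")
    cpos = cmap.positions(chrom)
    common, xs, xc = _common_scaffold(spos, cpos)
    if len(common) < 2:
        raise Rejection("no_common_markers")
    peak = qtl.peak_cm
    lefts = [i for i, m in enumerate(common) if xs[i] <= peak]
    rights = [i for i, m in enumerate(common) if xs[i] >= peak]
    if not lefts or not rights:
        raise Rejection("no_common_markers")

    best = None  # (discrepancy, span, li, rj)
    for li in reversed(lefts):           # nearest-first, widening outward
        for rj in rights:
            if rj <= li:
                continue
            ds = xs[rj] - xs[li]
            dc = xc[rj] - xc[li]
            if ds <= 0 or dc <= 0:
                continue
            ratio = max(dc / ds, ds / dc)
            if ratio > cfg.max_ratio:
                continue
            disc = abs(math.log(dc / ds))
            cand = (disc, ds, li, rj)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise Rejection("no_feasible_context")
    _, _, li, rj = best
    return ProjectionContext(
        left_marker=common[li],
        right_marker=common[rj],
        source_left=float(xs[li]),
        source_right=float(xs[rj]),
        consensus_left=float(xc[li]),
        consensus_right=float(xc[rj]),
        scaffold_source=tuple(xs),
        scaffold_consensus=tuple(xc),
    )


def _transform(x: float, ctx: ProjectionContext) -> float:
    if ctx.source_left <= x <= ctx.source_right:
        return ctx.consensus_left + (x - ctx.source_left) * ctx.scale
    # outside the context: use the nearest flanking common interval
    xs = np.asarray(ctx.scaffold_source, dtype=float)
    xc = np.asarray(ctx.scaffold_consensus, dtype=float)
    if len(xs) >= 2:
        return float(_interp_with_extrapolation(np.array([x]), xs, xc)[0])
    return ctx.consensus_left + (x - ctx.source_left) * ctx.scale


def project_qtl(
    qtl: QTLRecord, context: ProjectionContext, cfg: ProjectionConfig | None = None
) -> ProjectedQTL:
    """Map peak and CI onto the consensus map through ``context``."""
    cfg = cfg or ProjectionConfig()
    if context.source_right - context.source_left <= 0:
        return ProjectedQTL(qtl, status="rejected", reason="degenerate_context")
    peak = _transform(qtl.peak_cm, context)
    lo = _transform(qtl.ci_start_cm, context) if qtl.ci_start_cm is not None else peak
    hi = _transform(qtl.ci_end_cm, context) if qtl.ci_end_cm is not None else peak
    lo, hi = min(lo, hi), max(lo, hi)
    lo, peak, hi = lo, min(max(peak, lo), hi), hi
    if hi - lo > cfg.max_ci_cm:
        return ProjectedQTL(qtl, status="rejected", reason="large_CI")
    return ProjectedQTL(
        source=qtl,
        consensus_chromosome=qtl.chromosome,
        peak_cm=peak,
        ci_start_cm=lo,
        ci_end_cm=hi,
        context=context,
        status="projected",
    )


def project_all(
    qtls: Iterable[QTLRecord],
    maps: Mapping[str, GeneticMap],
    cmap: ConsensusMap,
    cfg: ProjectionConfig | None = None,
) -> tuple[list[ProjectedQTL], dict]:
    """Batch driver: project every usable record; account for every failure.

    ``maps`` is keyed by study_id. The report counts records per rejection
    reason and per chromosome; ``total == incomplete + rejected + projected``.
    """
    cfg = cfg or ProjectionConfig()
    out: list[ProjectedQTL] = []
    report = {
        "total": 0,
        "incomplete": 0,
        "usable": 0,
        "projected": 0,
        "rejected": 0,
        "reasons": {},
        "per_chromosome": {},
    }
    for qtl in qtls:
        report["total"] += 1
        chrom_stats = report["per_chromosome"].setdefault(
            qtl.chromosome, {"total": 0, "projected": 0}
        )
        chrom_stats["total"] += 1
        if "unprojectable" in qtl.flags or not qtl.complete:
            report["incomplete"] += 1
            out.append(ProjectedQTL(qtl, status="rejected", reason="incomplete"))
            continue
        report["usable"] += 1
        smap = maps.get(qtl.study_id)
        if smap is None:
            report["rejected"] += 1
            report["reasons"]["no_source_map"] = report["reasons"].get("no_source_map", 0) + 1
            out.append(ProjectedQTL(qtl, status="rejected", reason="no_source_map"))
            continue
        try:
            ctx = select_projection_context(qtl, smap, cmap, cfg)
        except Rejection as rej:
            report["rejected"] += 1
            report["reasons"][rej.reason] = report["reasons"].get(rej.reason, 0) + 1
            out.append(ProjectedQTL(qtl, status="rejected", reason=rej.reason))
            continue
        proj = project_qtl(qtl, ctx, cfg)
        if proj.projected:
            report["projected"] += 1
            chrom_stats["projected"] += 1
        else:
            report["rejected"] += 1
            report["reasons"][proj.reason] = report["reasons"].get(proj.reason, 0) + 1
        out.append(proj)
    return out, report


def projected_to_frame(projected: Sequence[ProjectedQTL]):
    import pandas as pd

    rows = []
    for p in projected:
        rows.append(
            {
                "qtl_id": p.source.qtl_id,
                "study_id": p.source.study_id,
                "chromosome": p.source.chromosome,
                "stress": p.source.stress,
                "status": p.status,
                "reason": p.reason,
                "peak_cm": p.peak_cm,
                "ci_start_cm": p.ci_start_cm,
                "ci_end_cm": p.ci_end_cm,
                "lod": p.source.lod,
                "pve": p.source.pve,
                "context_left": p.context.left_marker if p.context else None,
                "context_right": p.context.right_marker if p.context else None,
                "scale": p.context.scale if p.context else None,
            }
        )
    return pd.DataFrame(rows)
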