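"""QTL record model, tabular I/O, validation, imputation and CI estimation.

A :class:`QTLRecord` is one published QTL: its study, mapping population,
stress class, genetic coordinates (peak and 95% CI in cM on the source map),
LOD score and PVE (percentage of phenotypic variance explained, printed as a
percent in the literature and stored that way here).

Missing fields are imputed with the field's conventional defaults (LOD 3.0,
PVE 10, peak at the flanking-marker midpoint), and missing 95% CIs are
estimated from population size and PVE with the Darvasi–Soller-lineage
population-specific equation CI = k / (N · R²), R² as a proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

#: The seven stress codes used on records. "D+H" is combined drought+heat and
#: expands to {DS, HS} only when tallying stress classes, never on the record.
STRESS_CODES = ("DS", "HS", "D+H", "SS", "WS", "PHS", "AS")

#: Aliases seen in the literature (aluminium printed as "AL" in some tables).
STRESS_ALIASES = {"AL": "AS", "D + H": "D+H", "DH": "D+H"}

POPULATION_TYPES = ("F2", "BC", "DH", "RIL", "other")

#: The 21 chromosomes of hexaploid bread wheat.
WHEAT_CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")

#: Canonical column order of a QTL table.
QTL_COLUMNS = (
    "qtl_id",
    "study_id",
    "population_type",
    "population_size",
    "stress",
    "trait",
    "chromosome",
    "left_marker",
    "right_marker",
    "peak_cm",
    "ci_start_cm",
    "ci_end_cm",
    "lod",
    "pve",
)

MANDATORY_COLUMNS = ("study_id", "chromosome", "left_marker", "right_marker")


def normalize_stress(code: str) -> str:
    code = str(code).strip()
    return STRESS_ALIASES.get(code, code)


@dataclass(frozen=True)
class QTLRecord:
    """One published QTL with its genetic coordinates on the source map."""

    qtl_id: str
    study_id: str
    population_type: str
    population_size: int
    stress: str
    trait: str
    chromosome: str
    left_marker: str
    right_marker: str
    peak_cm: float | None = None
    ci_start_cm: float | None = None
    ci_end_cm: float | None = None
    lod: float | None = None
    pve: float | None = None
    #: provenance flags, e.g. {"lod_imputed", "ci_estimated", "unprojectable"}
    flags: frozenset = field(default_factory=frozenset, compare=False)

    def with_flags(self, *new: str) -> "QTLRecord":
        return replace(self, flags=self.flags | frozenset(new))

    @property
    def ci_width_cm(self) -> float | None:
        if self.ci_start_cm is None or self.ci_end_cm is None:
            return None
        return self.ci_end_cm - self.ci_start_cm

    @property
    def complete(self) -> bool:
        """True when peak, CI, LOD and PVE are all present."""
        return all(
            v is not None
            for v in (self.peak_cm, self.ci_start_cm, self.ci_end_cm, self.lod, self.pve)
        )


@dataclass(frozen=True)
class CIEstimationConfig:
    """Population-specific constants k for CI = k / (N · R²).

    Defaults follow the Darvasi–Soller-lineage literature: 530 for F2 and
    backcross, 287 for doubled haploids, 163 for RILs. Populations typed
    "other" fall back to the DH constant. All configurable.
    """

    constant_by_population: Mapping[str, float] = field(
        default_factory=lambda: {"F2": 530.0, "BC": 530.0, "DH": 287.0, "RIL": 163.0, "other": 287.0}
    )

    def constant(self, population_type: str) -> float:
        try:
            return self.constant_by_population[population_type]
        except KeyError:
            raise KeyError(f"no CI constant configured for population type {population_type!r}")


class ReadResult(NamedTuple):
    records: list
    rejects: pd.DataFrame  # columns: row, qtl_id, reason


class MissingColumnError(ValueError):
    pass


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _validate_row(row: dict) -> str | None:
    """Return a rejection reason for an invalid row, or None when valid."""
    chrom = str(row["chromosome"]).strip()
    if chrom not in WHEAT_CHROMOSOMES:
        return "unknown chromosome"
    stress = normalize_stress(row["stress"])
    if stress not in STRESS_CODES:
        return "unknown stress code"
    if str(row.get("population_type", "other")) not in POPULATION_TYPES:
        return "unknown population type"
    try:
        n = int(row["population_size"])
    except (TypeError, ValueError):
        return "bad population size"
    if n < 2:
        return "population size < 2"
    try:
        lo, hi = _opt_float(row.get("ci_start_cm")), _opt_float(row.get("ci_end_cm"))
        peak = _opt_float(row.get("peak_cm"))
        pve = _opt_float(row.get("pve"))
    except (TypeError, ValueError):
        return "non-numeric coordinate"
    if lo is not None and hi is not None and lo > hi:
        return "inverted CI"
    if peak is not None and peak < 0:
        return "negative peak"
    if pve is not None and not (0 < pve <= 100):
        return "PVE out of (0, 100]"
    return None


def read_qtl_table(path, sep: str = "\t") -> ReadResult:
    """Read a QTL table (TSV by default, header required).

    Rows that fail validation are collected into the ``rejects`` report with a
    reason, never silently dropped. Missing mandatory columns raise
    :class:`MissingColumnError` naming the column.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"mandatory column missing: {col!r}")
    records: list[QTLRecord] = []
    rejects: list[dict] = []
    for i, raw in enumerate(df.to_dict("records")):
        row = {k: (None if pd.isna(v) else v) for k, v in raw.items()}
        row.setdefault("qtl_id", f"row{i}")
        row.setdefault("population_type", "other")
        row.setdefault("population_size", 2)
        row.setdefault("stress", "DS")
        row.setdefault("trait", "")
        reason = _validate_row(row)
        if reason is not None:
            rejects.append({"row": i, "qtl_id": row.get("qtl_id"), "reason": reason})
            continue
        records.append(
            QTLRecord(
                qtl_id=str(row["qtl_id"]),
                study_id=str(row["study_id"]),
                population_type=str(row["population_type"]),
                population_size=int(row["population_size"]),
                stress=normalize_stress(row["stress"]),
                trait="" if row.get("trait") is None else str(row["trait"]),
                chromosome=str(row["chromosome"]).strip(),
                left_marker=str(row["left_marker"]),
                right_marker=str(row["right_marker"]),
                peak_cm=_opt_float(row.get("peak_cm")),
                ci_start_cm=_opt_float(row.get("ci_start_cm")),
                ci_end_cm=_opt_float(row.get("ci_end_cm")),
                lod=_opt_float(row.get("lod")),
                pve=_opt_float(row.get("pve")),
            )
        )
    rej = pd.DataFrame(rejects, columns=["row", "qtl_id", "reason"])
    return ReadResult(records, rej)


def records_to_frame(records: Iterable[QTLRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in QTL_COLUMNS}
        rows.append(d)
    return pd.DataFrame(rows, columns=list(QTL_COLUMNS))


def write_qtl_table(records: Iterable[QTLRecord], path, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Imputation and CI estimation
# ---------------------------------------------------------------------------

DEFAULT_LOD = 3.0
DEFAULT_PVE = 10.0


def impute_defaults(record: QTLRecord, source_map=None) -> QTLRecord:
    """Fill missing LOD (3.0), PVE (10) and peak (flanking-marker midpoint).

    ``source_map`` is the study's :class:`~mastqtl.consensus_map.GeneticMap`;
    it is only consulted when the peak is missing. Present values are never
    touched; each imputation is recorded in ``flags``. When the peak is
    missing and a flanking marker cannot be resolved on the source map, the
    record is flagged ``unprojectable``.
    """
    flags = []
    upd: dict = {}
    if record.lod is None:
        upd["lod"] = DEFAULT_LOD
        flags.append("lod_imputed")
    if record.pve is None:
        upd["pve"] = DEFAULT_PVE
        flags.append("pve_imputed")
    if record.peak_cm is None:
        left = right = None
        if source_map is not None:
            left = source_map.position(record.chromosome, record.left_marker)
            right = source_map.position(record.chromosome, record.right_marker)
        if left is None or right is None:
            flags.append("unprojectable")
        else:
            upd["peak_cm"] = (left + right) / 2.0
            flags.append("peak_imputed")
    out = replace(record, **upd) if upd else record
    return out.with_flags(*flags) if flags else out


def estimate_ci(record: QTLRecord, cfg: CIEstimationConfig | None = None) -> QTLRecord:
    """Estimate a missing 95% CI as k / (N · R²) centred on the peak.

    ``k`` is the population-specific constant from ``cfg``; R² is the PVE as a
    proportion. No-op when the original CI is present. The left endpoint is
    floored at 0 cM. Records with PVE = 0 or no usable peak are flagged
    ``unprojectable``.
    """
    if record.ci_start_cm is not None and record.ci_end_cm is not None:
        return record
    cfg = cfg or CIEstimationConfig()
    if record.pve is None or record.pve <= 0 or record.peak_cm is None:
        return record.with_flags("unprojectable")
    k = cfg.constant(record.population_type)
    width = k / (record.population_size * (record.pve / 100.0))
    lo = max(0.0, record.peak_cm - width / 2.0)
    hi = record.peak_cm + width / 2.0
    return replace(record, ci_start_cm=lo, ci_end_cm=hi).with_flags("ci_estimated")


def prepare_records(
    records: Iterable[QTLRecord],
    source_maps: Mapping[str, object] | None = None,
    cfg: CIEstimationConfig | None = None,
) -> list[QTLRecord]:
    """impute_defaults + estimate_ci for a batch; maps keyed by study_id."""
    out = []
    for r in records:
        smap = None if source_maps is None else source_maps.get(r.study_id)
        out.append(estimate_ci(impute_defaults(r, smap), cfg))
    return out
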