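"""Record validation, table round-trips, imputation and CI estimation."""

import math

import pandas as pd
import pytest

from mastqtl.consensus_map import GeneticMap
from mastqtl.qtl_data import (
    CIEstimationConfig,
    MissingColumnError,
    QTLRecord,
    estimate_ci,
    impute_defaults,
    prepare_records,
    read_qtl_table,
    records_to_frame,
    write_qtl_table,
)


def make_record(**kw):
    base = dict(
        qtl_id="q1",
        study_id="s1",
        population_type="RIL",
        population_size=163,
        stress="DS",
        trait="yield",
        chromosome="3B",
        left_marker="L",
        right_marker="R",
        peak_cm=15.0,
        ci_start_cm=10.0,
        ci_end_cm=20.0,
        lod=5.2,
        pve=18.0,
    )
    base.update(kw)
    return QTLRecord(**base)


TABLE = """qtl_id\tstudy_id\tpopulation_type\tpopulation_size\tstress\ttrait\tchromosome\tleft_marker\tright_marker\tpeak_cm\tci_start_cm\tci_end_cm\tlod\tpve
q1\ts1\tRIL\t163\tDS\tgy\t3B\tm1\tm2\t10.0\t5.0\t15.0\t3.5\t12.0
q2\ts1\tDH\t150\tHS\tgy\t1A\tm3\tm4\t20.0\t18.0\t25.0\t\t
q3\ts2\tF2\t500\tSS\tgy\t7D\tm5\tm6\t\t\t\t4.0\t9.0
"""


def test_read_well_formed_table(tmp_path):
    p = tmp_path / "q.tsv"
    p.write_text(TABLE)
    records, rejects = read_qtl_table(p)
    assert len(records) == 3 and len(rejects) == 0
    assert records[0].peak_cm == 10.0
    assert records[1].lod is None  # blank stays missing, not zero


@pytest.mark.parametrize(
    "field,value,reason",
    [
        ("chromosome", "8A", "unknown chromosome"),
        ("ci_start_cm", "30.0", "inverted CI"),  # > ci_end 15
        ("stress", "XX", "unknown stress code"),
        ("population_size", "1", "population size < 2"),
    ],
)
def test_invalid_rows_are_rejected_with_reason(tmp_path, field, value, reason):
    df = pd.read_csv(__import__("io").StringIO(TABLE), sep="\t", dtype=str)
    df.loc[0, field] = value
    p = tmp_path / "q.tsv"
    df.to_csv(p, sep="\t", index=False)
    records, rejects = read_qtl_table(p)
    assert len(records) == 2
    assert rejects["reason"].tolist() == [reason]


def test_missing_mandatory_column_is_hard_error(tmp_path):
    df = pd.read_csv(__import__("io").StringIO(TABLE), sep="\t").drop(columns=["left_marker"])
    p = tmp_path / "q.tsv"
    df.to_csv(p, sep="\t", index=False)
    with pytest.raises(MissingColumnError, match="left_marker"):
        read_qtl_table(p)


def test_round_trip_preserves_all_values(tmp_path):
    p = tmp_path / "q.tsv"
    p.write_text(TABLE)
    records, _ = read_qtl_table(p)
    out = tmp_path / "out.tsv"
    write_qtl_table(records, out)
    again, rejects = read_qtl_table(out)
    assert len(rejects) == 0
    assert records_to_frame(records).equals(records_to_frame(again))


def test_aluminium_alias_normalized(tmp_path):
    p = tmp_path / "q.tsv"
    p.write_text(TABLE.replace("DS\tgy", "AL\tgy", 1))
    records, rejects = read_qtl_table(p)
    assert len(rejects) == 0
    assert records[0].stress == "AS"


class TestImputeDefaults:
    def test_missing_lod_and_pve_get_defaults(self):
        r = impute_defaults(make_record(lod=None, pve=None))
        assert r.lod == 3.0 and r.pve == 10.0
        assert {"lod_imputed", "pve_imputed"} <= set(r.flags)

    def test_missing_peak_is_flanking_midpoint(self):
        smap = GeneticMap(
            "s1",
            pd.DataFrame(
                {"chromosome": ["3B", "3B"], "marker": ["L", "R"], "cm": [10.0, 20.0]}
            ),
        )
        r = impute_defaults(make_record(peak_cm=None), smap)
        assert r.peak_cm == 15.0 and "peak_imputed" in r.flags

    def test_present_values_untouched(self):
        r = make_record()
        assert impute_defaults(r) == r

    def test_unresolvable_flank_flags_unprojectable(self):
        smap = GeneticMap(
            "s1", pd.DataFrame({"chromosome": ["3B"], "marker": ["L"], "cm": [10.0]})
        )
        r = impute_defaults(make_record(peak_cm=None), smap)
        assert "unprojectable" in r.flags


class TestEstimateCI:
    @pytest.mark.parametrize(
        "ptype,k,n,pve,width",
        [("RIL", 163.0, 163, 10.0, 10.0), ("F2", 530.0, 530, 10.0, 10.0)],
    )
    def test_width_follows_population_equation(self, ptype, k, n, pve, width):
        r = make_record(
            population_type=ptype,
            population_size=n,
            pve=pve,
            ci_start_cm=None,
            ci_end_cm=None,
        )
        out = estimate_ci(r)
        assert math.isclose(out.ci_end_cm - out.ci_start_cm, width)
        assert "ci_estimated" in out.flags

    def test_existing_ci_is_noop(self):
        r = make_record()
        assert estimate_ci(r) == r

    def test_left_endpoint_floored_at_zero(self):
        r = make_record(peak_cm=1.0, ci_start_cm=None, ci_end_cm=None, pve=10.0)
        out = estimate_ci(r)
        assert out.ci_start_cm == 0.0

    def test_width_decreases_in_n_and_pve(self):
        widths = []
        for n, pve in [(100, 10.0), (200, 10.0), (200, 20.0)]:
            r = make_record(
                population_size=n, pve=pve, ci_start_cm=None, ci_end_cm=None
            )
            out = estimate_ci(r)
            widths.append(out.ci_end_cm - out.ci_start_cm)
        assert widths[0] > widths[1] > widths[2]

    def test_custom_constants_respected(self):
        cfg = CIEstimationConfig({"RIL": 100.0})
        r = make_record(
            population_size=100, pve=10.0, ci_start_cm=None, ci_end_cm=None
        )
        out = estimate_ci(r, cfg)
        assert math.isclose(out.ci_end_cm - out.ci_start_cm, 10.0)


def test_prepared_records_are_complete(study_data):
    """After imputation + CI estimation, every non-rejected record has
    peak, CI, LOD and PVE (or is explicitly flagged unprojectable)."""
    recs = prepare_records(study_data.qtls, study_data.study_maps)
    for r in recs:
        assert r.complete or "unprojectable" in r.flags
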