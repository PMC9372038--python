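"""Physical anchoring and the cM-to-bp peak-position rule."""

import pandas as pd
import pytest

from mastqtl.consensus_map import GeneticMap, build_consensus
from mastqtl.meta_analysis import MQTL
from mastqtl.physical_anchor import (
    MarkerPhysicalTable,
    PhysicalInterval,
    Unanchored,
    anchor_mqtl,
    peak_position_bp,
    to_bed,
)


def mqtl(ci_start, ci_end, chrom="1A", name="MQTL1A.1"):
    pos = (ci_start + ci_end) / 2
    return MQTL(
        name=name,
        chromosome=chrom,
        position_cm=pos,
        ci_start_cm=ci_start,
        ci_end_cm=ci_end,
        member_ids=("q1", "q2"),
        n_studies=2,
        mean_lod=4.0,
        mean_pve=11.0,
        stress_tally={"DS": 2},
    )


@pytest.fixture
def cmap():
    return build_consensus(
        [
            GeneticMap(
                "m",
                pd.DataFrame(
                    {
                        "chromosome": "1A",
                        "marker": ["a", "b", "c", "d"],
                        "cm": [0.0, 10.0, 20.0, 30.0],
                    }
                ),
            )
        ]
    )


def phys(rows):
    return MarkerPhysicalTable(pd.DataFrame(rows, columns=["marker", "chromosome", "bp"]))


class TestPeakPosition:
    def test_hand_evaluated_example(self):
        assert peak_position_bp(1_000_000, 2_000_000, 10.0, 12.0, 1.0) == 1_250_000

    def test_ci_equal_to_span_gives_midpoint(self):
        assert peak_position_bp(100, 300, 5.0, 9.0, 4.0) == 200

    def test_zero_width_genetic_ci_gives_bp_midpoint(self):
        assert peak_position_bp(100, 301, 154.63, 154.63, 0.0) == 200

    def test_clamped_into_interval(self):
        # very wide ci95 would overshoot end_bp without clamping
        assert peak_position_bp(100, 200, 10.0, 10.1, 50.0) == 200


class TestAnchor:
    def test_flank_markers_resolve_directly(self, cmap):
        table = phys(
            [("b", "1A", 1_000), ("c", "1A", 5_000)]
        )
        iv = anchor_mqtl(mqtl(10.0, 20.0), cmap, table)
        assert (iv.start_bp, iv.end_bp) == (1_000, 5_000)
        assert iv.flags == ()

    def test_missing_left_uses_next_resolvable_with_flag(self, cmap):
        table = phys([("c", "1A", 5_000), ("d", "1A", 9_000)])
        iv = anchor_mqtl(mqtl(10.0, 20.0), cmap, table)
        assert iv.start_bp == 5_000 and "extended_left" in iv.flags

    def test_no_physical_markers_unanchored(self, cmap):
        with pytest.raises(Unanchored, match="no_physical_markers"):
            anchor_mqtl(mqtl(10.0, 20.0), cmap, phys([]))

    def test_markers_on_other_chromosome_unusable(self, cmap):
        table = phys([("b", "2B", 1_000), ("c", "2B", 5_000)])
        with pytest.raises(Unanchored):
            anchor_mqtl(mqtl(10.0, 20.0), cmap, table)

    def test_monotone_containment(self, cmap):
        """A genetic CI nested in another yields a nested physical interval
        when both resolve through the same marker set."""
        table = phys(
            [("a", "1A", 100), ("b", "1A", 1_000), ("c", "1A", 5_000), ("d", "1A", 9_000)]
        )
        inner = anchor_mqtl(mqtl(10.0, 20.0), cmap, table)
        outer = anchor_mqtl(mqtl(0.0, 30.0), cmap, table)
        assert outer.start_bp <= inner.start_bp <= inner.end_bp <= outer.end_bp

    def test_peak_always_inside(self, cmap):
        table = phys([("b", "1A", 1_000), ("c", "1A", 5_000)])
        iv = anchor_mqtl(mqtl(10.0, 20.0), cmap, table)
        assert iv.start_bp <= iv.peak_bp <= iv.end_bp


def test_bed_export_zero_based_half_open(cmap):
    table = phys([("b", "1A", 1_000), ("c", "1A", 5_000)])
    m = mqtl(10.0, 20.0)
    iv = anchor_mqtl(m, cmap, table)
    bed = to_bed([m], {m.name: iv})
    row = bed.iloc[0]
    assert (row["chromStart"], row["chromEnd"]) == (999, 5_000)
    assert row["score"] == pytest.approx(11.0)


class TestPeakFormulaProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    bp = st.integers(min_value=1, max_value=10**9)
    cm = st.floats(min_value=0.0, max_value=500.0, allow_nan=False)

    @given(start=bp, span=st.integers(min_value=0, max_value=10**8), start_cm=cm,
           dcm=st.floats(min_value=0.0, max_value=100.0), ci=cm)
    @settings(derandomize=True, max_examples=200)
    def test_peak_always_inside_interval(self, start, span, start_cm, dcm, ci):
        end = start + span
        peak = peak_position_bp(start, end, start_cm, start_cm + dcm, ci)
        assert start <= peak <= end

    @given(start=bp, span=st.integers(min_value=0, max_value=10**8), start_cm=cm,
           dcm=st.floats(min_value=1e-6, max_value=100.0))
    @settings(derandomize=True, max_examples=100)
    def test_midpoint_identity_when_ci_equals_span(self, start, span, start_cm, dcm):
        end = start + span
        peak = peak_position_bp(start, end, start_cm, start_cm + dcm, dcm)
        # identity up to 1 bp: float division (span/dcm)*dcm/2 can land a
        # half-ulp either side of the exact midpoint before integer rounding
        assert abs(peak - (start + end) / 2) <= 1


def test_interval_invariants():
    with pytest.raises(ValueError):
        PhysicalInterval("1A", 10, 5, 7)
    with pytest.raises(ValueError):
        PhysicalInterval("1A", 10, 20, 25)
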