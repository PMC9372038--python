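"""MAST selection, gene windows, fold-change DEG calls and ranking."""

import numpy as np
import pandas as pd
import pytest

from mastqtl.candidate_genes import (
    DEGCall,
    ExpressionDataset,
    GeneModel,
    call_degs,
    gene_window,
    mine_genes,
    rank_candidates,
    read_gene_models,
    select_mast_mqtls,
    write_gff3,
)
from mastqtl.meta_analysis import MQTL
from mastqtl.physical_anchor import PhysicalInterval

MB = 1_000_000


def mqtl(tally, n_members=10, name="MQTL1A.1"):
    return MQTL(
        name=name,
        chromosome="1A",
        position_cm=10.0,
        ci_start_cm=9.0,
        ci_end_cm=11.0,
        member_ids=tuple(f"q{i}" for i in range(n_members)),
        n_studies=5,
        mean_lod=4.0,
        mean_pve=10.0,
        stress_tally=tally,
    )


class TestMastSelection:
    def test_six_class_tally_selected(self):
        m = mqtl({c: 1 for c in ("AS", "DS", "HS", "SS", "WS", "PHS")})
        assert select_mast_mqtls([m]) == [m]

    def test_four_classes_not_selected_at_threshold_five(self):
        m = mqtl({"DS": 3, "HS": 1, "PHS": 2, "SS": 4})
        assert select_mast_mqtls([m]) == []

    def test_combined_drought_heat_expansion_counts_two(self):
        # a tally built from D+H-only members covers exactly DS and HS
        m = mqtl({"DS": 4, "HS": 4})
        assert m.n_stress_classes == 2

    def test_min_member_threshold(self):
        m = mqtl({c: 2 for c in ("AS", "DS", "HS", "SS", "WS")}, n_members=5)
        assert select_mast_mqtls([m], min_members=9) == []
        assert select_mast_mqtls([m], min_members=2) == [m]


class TestGeneWindow:
    def test_narrow_ci_used_directly(self):
        iv = PhysicalInterval("1A", 10 * MB, 11 * MB + MB // 2, 11 * MB)
        assert gene_window(iv) is iv

    def test_wide_ci_becomes_peak_window(self):
        iv = PhysicalInterval("1A", 5 * MB, 55 * MB, 30 * MB)
        w = gene_window(iv)
        assert (w.start_bp, w.end_bp) == (29 * MB, 31 * MB)

    def test_clipped_at_chromosome_start(self):
        iv = PhysicalInterval("1A", 1, 50 * MB, 400_000)
        w = gene_window(iv)
        assert w.start_bp == 1
        assert w.end_bp == 400_000 + MB

    def test_width_bounded(self):
        iv = PhysicalInterval("1A", 5 * MB, 55 * MB, 30 * MB)
        assert gene_window(iv).width_bp <= max(iv.width_bp, 2 * MB + 1)


def test_mine_genes_any_overlap_and_dedup():
    window = PhysicalInterval("1A", 1_000, 2_000, 1_500)
    ann = [
        GeneModel("g_in", "1A", 1_100, 1_200),
        GeneModel("g_edge", "1A", 1_990, 2_300),  # straddles the edge
        GeneModel("g_out", "1A", 2_001, 2_300),
        GeneModel("g_chr", "2B", 1_100, 1_200),
    ]
    out = mine_genes(window, ann + ann)  # duplicated annotation
    assert [g.gene_id for g in out] == ["g_in", "g_edge"]
    assert mine_genes(window, []) == []


def test_gff3_round_trip(tmp_path):
    genes = [GeneModel("g1", "1A", 100, 500, "+", "kinase"), GeneModel("g2", "2B", 50, 80, "-")]
    p = tmp_path / "genes.gff3"
    write_gff3(genes, p)
    again = read_gene_models(p)
    assert again == genes


def dataset(values, log2=True, dataset_id="d1"):
    """Two control + two stress samples; one 'stress' condition."""
    genes = list(values)
    mat = pd.DataFrame(
        {
            "c1": [values[g][0] for g in genes],
            "c2": [values[g][0] for g in genes],
            "s1": [values[g][1] for g in genes],
            "s2": [values[g][1] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "sample": ["c1", "c2", "s1", "s2"],
            "condition": ["control", "control", "stress", "stress"],
            "is_control": [True, True, False, False],
        }
    )
    return ExpressionDataset(dataset_id, mat, meta, log2=log2)


class TestCallDegs:
    def test_twofold_up_called(self):
        calls, _ = call_degs(["g"], dataset({"g": (1.0, 3.0)}))
        assert len(calls) == 1
        assert calls[0].log2fc == pytest.approx(2.0) and calls[0].direction == "up"

    def test_subthreshold_change_not_called(self):
        calls, _ = call_degs(["g"], dataset({"g": (1.0, 1.58)}))
        assert calls == []

    def test_raw_tpm_with_pseudocount(self):
        calls, _ = call_degs(["g"], dataset({"g": (0.0, 4.0)}, log2=False), pseudo=0.01)
        assert calls[0].log2fc == pytest.approx(np.log2(4.01 / 0.01), abs=1e-9)

    def test_absent_gene_logged_not_fatal(self):
        calls, missing = call_degs(["g", "ghost"], dataset({"g": (1.0, 3.0)}))
        assert missing == ["ghost"] and len(calls) == 1

    def test_stored_calls_always_clear_threshold(self):
        with pytest.raises(ValueError):
            DEGCall("g", "d", "c", 0.5, "up")


class TestRankCandidates:
    def calls(self, spec):
        out = []
        for gene, datasets in spec.items():
            for d in datasets:
                out.append(DEGCall(gene, d, "stress", 2.0, "up"))
        return out

    def test_promising_threshold(self):
        ranked = rank_candidates(
            self.calls({"a": ["d1", "d2", "d3", "d4"], "b": ["d1"], "c": ["d1", "d2", "d3"]})
        )
        flags = dict(zip(ranked["gene_id"], ranked["promising"]))
        assert flags == {"a": True, "b": False, "c": True}
        assert ranked.iloc[0]["gene_id"] == "a"  # 4/4 datasets ranks first

    def test_dataset_order_invariance(self):
        c1 = self.calls({"a": ["d1", "d2", "d3"], "b": ["d2"]})
        r1 = rank_candidates(c1)
        r2 = rank_candidates(list(reversed(c1)))
        assert r1.equals(r2)

    def test_mixed_direction_summary(self):
        calls = [
            DEGCall("g", "d1", "t1", 2.0, "up"),
            DEGCall("g", "d2", "t2", -1.5, "down"),
            DEGCall("g", "d3", "t1", 1.2, "up"),
        ]
        ranked = rank_candidates(calls)
        assert ranked.iloc[0]["direction"] == "mixed"


def test_planted_promising_genes_recovered_exactly(omics, scenario):
    """Genes planted with |log2FC| >= threshold in exactly >= 3 datasets are
    the promising set; decoys planted in a single dataset are not."""
    genes = list(omics.truth_promising) + list(omics.truth_decoys)
    calls = []
    for ds in omics.expression:
        c, _ = call_degs(genes, ds)
        calls.extend(c)
    ranked = rank_candidates(calls, min_datasets=scenario.promising_in_datasets)
    promising = set(ranked.loc[ranked["promising"], "gene_id"])
    assert promising == set(omics.truth_promising)
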