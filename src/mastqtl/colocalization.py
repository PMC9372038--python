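"""Overlap MQTL physical intervals with GWAS MTAs and known stress genes.

An MQTL is *GWAS-validated* when at least one significant marker-trait
association (MTA) falls inside its physical interval (closed-interval
containment on 1-based coordinates; an optional +/- window widens the
interval, default 0). Known-gene co-localization uses any-overlap semantics
between the gene span and the MQTL interval. Interval indexing is backed by
:mod:`intervaltree`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .physical_anchor import PhysicalInterval

MTA_COLUMNS = ("marker", "chromosome", "bp", "stress", "study_id")
GENE_COLUMNS = ("gene", "chromosome", "start_bp", "end_bp", "stress")


def normalize_chromosome(label: str) -> str:
    """Normalize chromosome spellings: 'chr1A', 'Chr_1A', '1a' -> '1A'."""
    s = re.sub(r"^[Cc]hr[_.]?", "", str(label).strip())
    return s.upper()


def read_mta_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    return df


def read_known_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    return df


def _trees(intervals: Mapping[str, PhysicalInterval], window: int) -> dict:
    trees: dict[str, IntervalTree] = {}
    for name, iv in intervals.items():
        chrom = normalize_chromosome(iv.chromosome)
        tree = trees.setdefault(chrom, IntervalTree())
        # half-open internally: [start, end+1) makes the closed bp interval
        tree.addi(iv.start_bp - window, iv.end_bp + 1 + window, name)
    return trees


def overlap_mtas(
    intervals: Mapping[str, PhysicalInterval],
    mtas: pd.DataFrame,
    window: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count MTAs inside each MQTL interval; validated ⇔ count >= 1.

    Returns (per-MQTL report, unresolved rows). Rows whose normalized
    chromosome matches no anchored MQTL chromosome are reported unresolved
    rather than dropped.
    """
    trees = _trees(intervals, window)
    counts = {name: 0 for name in intervals}
    unresolved = []
    for row in mtas.to_dict("records"):
        chrom = normalize_chromosome(row["chromosome"])
        if chrom not in trees:
            unresolved.append(row)
            continue
        for hit in trees[chrom][int(row["bp"])]:
            counts[hit.data] += 1
    report = pd.DataFrame(
        {
            "name": list(counts),
            "mta_count": [counts[n] for n in counts],
            "validated": [counts[n] >= 1 for n in counts],
        }
    )
    return report.sort_values("name").reset_index(drop=True), pd.DataFrame(unresolved)


def validated_fraction(report: pd.DataFrame) -> float:
    return float(report["validated"].mean()) if len(report) else 0.0


def overlap_known_genes(
    intervals: Mapping[str, PhysicalInterval],
    genes: pd.DataFrame,
    window: int = 0,
) -> pd.DataFrame:
    """Known genes overlapping each MQTL interval (any shared bp).

    Returns long-format rows (name, gene, stress, gene_start_bp, gene_end_bp).
    """
    trees = _trees(intervals, window)
    rows = []
    for row in genes.to_dict("records"):
        chrom = normalize_chromosome(row["chromosome"])
        if chrom not in trees:
            continue
        start, end = int(row["start_bp"]), int(row["end_bp"])
        for hit in trees[chrom].overlap(start, end + 1):
            rows.append(
                {
                    "name": hit.data,
                    "gene": row.get("gene"),
                    "stress": row.get("stress"),
                    "gene_start_bp": start,
                    "gene_end_bp": end,
                }
            )
    df = pd.DataFrame(rows, columns=["name", "gene", "stress", "gene_start_bp", "gene_end_bp"])
    return df.sort_values(["name", "gene"]).reset_index(drop=True)
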