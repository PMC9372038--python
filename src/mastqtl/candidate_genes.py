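"""MAST-MQTL selection, gene mining, fold-change DEG calling and ranking.

MQTLs conferring tolerance to at least ``min_stress_classes`` different
abiotic stresses (and built from at least ``min_members`` QTLs) are selected
for gene mining. Narrow MQTLs (physical CI <= 2 Mb) are mined over their
whole interval; wider ones over a 2 Mb window centred on the physical peak
(1 Mb either side). Differential expression across log2-TPM datasets uses a
pure fold-change rule: a gene is called in a condition when
|log2FC| = |mean(stress) - mean(control)| >= 1, i.e. a two-fold change.
Candidates are ranked by the number of datasets in which they are called;
genes called in >= ``min_datasets`` datasets are flagged *promising*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .meta_analysis import MQTL
from .physical_anchor import PhysicalInterval

MB = 1_000_000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    strand: str = "+"
    function: str = ""

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene features, ID attribute) or 5/6-col TSV."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or first.count("\t") == 8:
        return _read_gff3_genes(path)
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            gene_id=str(r["gene_id"]),
            chromosome=str(r["chromosome"]),
            start_bp=int(r["start_bp"]),
            end_bp=int(r["end_bp"]),
            strand=str(r.get("strand", "+")),
            function=str(r.get("function", "") or ""),
        )
        for r in df.to_dict("records")
    ]


def _read_gff3_genes(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}")),
                    chromosome=f[0],
                    start_bp=int(f[3]),
                    end_bp=int(f[4]),
                    strand=f[6] if f[6] in "+-" else "+",
                    function=attrs.get("description", ""),
                )
            )
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.function:
                attrs += f";description={g.function}"
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        "mastqtl",
                        "gene",
                        str(g.start_bp),
                        str(g.end_bp),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# MAST selection and gene mining
# ---------------------------------------------------------------------------


def select_mast_mqtls(
    mqtls: Sequence[MQTL], min_stress_classes: int = 5, min_members: int = 9
) -> list[MQTL]:
    """MQTLs with >= min_stress_classes distinct stresses and >= min_members QTLs."""
    return [
        m
        for m in mqtls
        if m.n_stress_classes >= min_stress_classes and m.n_members >= min_members
    ]


def gene_window(
    interval: PhysicalInterval,
    max_direct_bp: int = 2 * MB,
    flank_bp: int = MB,
    chromosome_length_bp: int | None = None,
) -> PhysicalInterval:
    """Mining window: whole CI if narrow, else peak +/- flank, clipped."""
    if interval.width_bp <= max_direct_bp:
        return interval
    start = max(1, interval.peak_bp - flank_bp)
    end = interval.peak_bp + flank_bp
    if chromosome_length_bp is not None:
        end = min(end, chromosome_length_bp)
    return PhysicalInterval(
        chromosome=interval.chromosome,
        start_bp=start,
        end_bp=end,
        peak_bp=min(max(interval.peak_bp, start), end),
        flags=interval.flags + ("peak_window",),
    )


def mine_genes(window: PhysicalInterval, annotation: Sequence[GeneModel]) -> list[GeneModel]:
    """Genes with any overlap with the window, de-duplicated by gene_id."""
    seen = set()
    out = []
    for g in annotation:
        if g.chromosome != window.chromosome or g.gene_id in seen:
            continue
        if g.end_bp >= window.start_bp and g.start_bp <= window.end_bp:
            out.append(g)
            seen.add(g.gene_id)
    return out


# ---------------------------------------------------------------------------
# Expression / DEG calling
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """genes x samples matrix of log2 TPM plus sample metadata.

    ``metadata`` columns: sample, condition, is_control (bool). Every
    non-control condition must have control samples to compare against.
    ``log2`` marks whether the matrix is already log2-transformed; raw TPM is
    transformed with a pseudocount at call time.
    """

    dataset_id: str
    matrix: pd.DataFrame
    metadata: pd.DataFrame
    log2: bool = True

    def __post_init__(self):
        if not self.metadata["is_control"].any():
            raise ValueError(f"{self.dataset_id}: no control samples")

    @classmethod
    def from_tsv(cls, matrix_path, metadata_path, dataset_id=None, log2=True):
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t")
        meta["is_control"] = meta["is_control"].astype(bool)
        return cls(dataset_id or str(matrix_path), mat, meta, log2=log2)


@dataclass(frozen=True)
class DEGCall:
    gene_id: str
    dataset_id: str
    condition: str
    log2fc: float
    direction: str  # up / down

    def __post_init__(self):
        if abs(self.log2fc) < 1:
            raise ValueError("DEG calls require |log2FC| >= 1")


def call_degs(
    genes: Iterable[str],
    dataset: ExpressionDataset,
    lfc_threshold: float = 1.0,
    pseudo: float = 0.01,
) -> tuple[list[DEGCall], list[str]]:
    """Fold-change DEG calls per non-control condition.

    Returns (calls, genes absent from the matrix). With raw-TPM input the
    matrix is log2(x + pseudo) transformed first.
    """
    mat = dataset.matrix
    if not dataset.log2:
        mat = np.log2(mat + pseudo)
    meta = dataset.metadata
    ctrl_samples = meta.loc[meta["is_control"], "sample"]
    ctrl = mat[list(ctrl_samples)].mean(axis=1)
    calls: list[DEGCall] = []
    missing: list[str] = []
    genes = [g for g in genes]
    present = [g for g in genes if g in mat.index]
    missing = [g for g in genes if g not in mat.index]
    for condition, grp in meta[~meta["is_control"]].groupby("condition"):
        mean_stress = mat[list(grp["sample"])].mean(axis=1)
        lfc = mean_stress - ctrl
        for g in present:
            v = float(lfc.loc[g])
            if abs(v) >= lfc_threshold:
                calls.append(
                    DEGCall(
                        gene_id=g,
                        dataset_id=dataset.dataset_id,
                        condition=str(condition),
                        log2fc=v,
                        direction="up" if v > 0 else "down",
                    )
                )
    return calls, missing


def rank_candidates(
    calls: Iterable[DEGCall], min_datasets: int = 3
) -> pd.DataFrame:
    """Rank genes by the number of datasets with at least one DEG call.

    Returns a frame (gene_id, n_datasets, max_abs_log2fc, direction,
    promising) sorted by dataset count then effect size; ``direction`` is
    up/down/mixed across that gene's calls. Stable and invariant to the
    order datasets are supplied in.
    """
    per_gene: dict[str, dict] = {}
    for c in calls:
        d = per_gene.setdefault(c.gene_id, {"datasets": set(), "lfcs": [], "dirs": set()})
        d["datasets"].add(c.dataset_id)
        d["lfcs"].append(c.log2fc)
        d["dirs"].add(c.direction)
    rows = []
    for gene_id in sorted(per_gene):
        d = per_gene[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "n_datasets": len(d["datasets"]),
                "max_abs_log2fc": max(abs(v) for v in d["lfcs"]),
                "direction": d["dirs"].pop() if len(d["dirs"]) == 1 else "mixed",
                "promising": len(d["datasets"]) >= min_datasets,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "n_datasets", "max_abs_log2fc", "direction", "promising"]
    )
    return df.sort_values(
        ["n_datasets", "max_abs_log2fc", "gene_id"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
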