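"""Pipeline orchestration, configuration, and the dataset-level summaries.

``run_pipeline`` executes the stages in order — read → impute/CI → consensus
→ project → meta-analysis → physical anchoring → co-localization → gene
mining → DEG calling → promoter scanning → ortho-MQTL detection → summaries
— writing each stage's TSV artifact plus a machine-readable run log with the
attrition counts at every step (collected → usable → projected → hotspots →
true MQTLs).

The summary helpers compute the descriptive statistics usual in meta-QTL
reports: per-chromosome/per-subgenome QTL shares, PVE and CI category
splits, per-subgenome marker densities (both the global markers-per-cM ratio
and the mean of per-chromosome densities, which differ whenever chromosome
lengths differ), and the CI fold-reduction of MQTLs relative to the initial
QTLs.
"""

from __future__ import annotations

import glob as _glob
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import (
    candidate_genes,
    colocalization,
    consensus_map,
    meta_analysis,
    ortho_mqtl,
    physical_anchor,
    projection,
    promoter_cre,
    qtl_data,
)


def percentage(part: float, total: float) -> float:
    """Share of total as a percent, 2 decimals; 0 when total is 0."""
    return round(100.0 * part / total, 2) if total else 0.0


def marker_density(n_markers: float, cm_length: float) -> float:
    """Markers per cM, 2 decimals; 0 when the map has no length."""
    return round(n_markers / cm_length, 2) if cm_length else 0.0


def subgenome(chromosome: str) -> str:
    """Subgenome letter of a wheat chromosome ('3B' -> 'B')."""
    return str(chromosome)[-1]


def summarize_inputs(records: Sequence, cmap=None) -> dict:
    """Descriptive tables for the collected QTLs (and optionally the map)."""
    df = qtl_data.records_to_frame(records)
    total = len(df)
    out: dict[str, pd.DataFrame] = {}

    per_chrom = (
        df.groupby("chromosome").size().rename("n_qtls").reset_index()
        if total
        else pd.DataFrame(columns=["chromosome", "n_qtls"])
    )
    per_chrom["pct"] = [percentage(n, total) for n in per_chrom.get("n_qtls", [])]
    out["per_chromosome"] = per_chrom

    if total:
        counts = df["chromosome"].map(subgenome).value_counts().sort_index()
        per_sg = pd.DataFrame({"subgenome": counts.index, "n_qtls": counts.values})
    else:
        per_sg = pd.DataFrame(columns=["subgenome", "n_qtls"])
    per_sg["pct"] = [percentage(n, total) for n in per_sg.get("n_qtls", [])]
    out["per_subgenome"] = per_sg

    pve = df["pve"].dropna() if total else pd.Series(dtype=float)
    out["pve_split"] = pd.DataFrame(
        {
            "category": ["<10", ">=10"],
            "n": [int((pve < 10).sum()), int((pve >= 10).sum())],
            "pct": [
                percentage(int((pve < 10).sum()), total),
                percentage(int((pve >= 10).sum()), total),
            ],
        }
    )
    if total:
        ciw = (df["ci_end_cm"] - df["ci_start_cm"]).dropna()
    else:
        ciw = pd.Series(dtype=float)
    out["ci_split"] = pd.DataFrame(
        {
            "category": [">10 cM", "<=10 cM"],
            "n": [int((ciw > 10).sum()), int((ciw <= 10).sum())],
            "pct": [
                percentage(int((ciw > 10).sum()), total),
                percentage(int((ciw <= 10).sum()), total),
            ],
        }
    )

    stresses = df["stress"].value_counts().sort_index() if total else pd.Series(dtype=int)
    out["per_stress"] = pd.DataFrame(
        {"stress": stresses.index, "n_qtls": stresses.values}
    )
    out["means"] = pd.DataFrame(
        {
            "statistic": ["mean_qtls_per_stress", "mean_qtls_per_chromosome"],
            "value": [
                round(total / len(meta_analysis.STRESS_CLASSES), 2) if total else 0.0,
                round(total / len(per_chrom), 2) if len(per_chrom) else 0.0,
            ],
        }
    )

    if cmap is not None:
        rows = []
        ent = cmap.entries
        for sg_name, sub in ent.groupby(ent["chromosome"].map(subgenome)):
            n = len(sub)
            length = float(
                sub.groupby("chromosome")["cm"].agg(lambda s: s.max() - s.min()).sum()
            )
            per_chrom_density = [
                marker_density(len(g), g["cm"].max() - g["cm"].min())
                for _, g in sub.groupby("chromosome")
            ]
            rows.append(
                {
                    "subgenome": sg_name,
                    "n_markers": n,
                    "cm_length": round(length, 2),
                    "markers_per_cm": marker_density(n, length),
                    "mean_chromosome_density": round(float(np.mean(per_chrom_density)), 2),
                }
            )
        out["map_per_subgenome"] = pd.DataFrame(rows)
        n_all = len(ent)
        len_all = float(
            ent.groupby("chromosome")["cm"].agg(lambda s: s.max() - s.min()).sum()
        )
        out["map_overall"] = pd.DataFrame(
            {
                "statistic": ["n_markers", "cm_length", "markers_per_cm"],
                "value": [n_all, round(len_all, 2), marker_density(n_all, len_all)],
            }
        )
    return out


def ci_fold_reduction(
    projected: Sequence, mqtls: Sequence, chromosome: str | None = None
) -> float:
    """mean(initial projected CI widths) / mean(MQTL CI widths)."""
    pw = [
        p.ci_width_cm
        for p in projected
        if p.projected and (chromosome is None or p.consensus_chromosome == chromosome)
    ]
    mw = [m.ci_width_cm for m in mqtls if chromosome is None or m.chromosome == chromosome]
    if not pw or not mw or np.mean(mw) == 0:
        return float("nan")
    return float(np.mean(pw) / np.mean(mw))


def summarize_mqtls(
    mqtls: Sequence, projected: Sequence, anchored: Mapping | None = None
) -> dict:
    out: dict[str, pd.DataFrame] = {}
    rows = []
    chroms = sorted({m.chromosome for m in mqtls})
    for c in chroms:
        sub = [m for m in mqtls if m.chromosome == c]
        rows.append(
            {
                "chromosome": c,
                "n_mqtls": len(sub),
                "fold_reduction": round(ci_fold_reduction(projected, sub, c), 2),
            }
        )
    out["per_chromosome"] = pd.DataFrame(rows, columns=["chromosome", "n_mqtls", "fold_reduction"])
    overall = ci_fold_reduction(projected, mqtls)
    out["overall"] = pd.DataFrame(
        {
            "statistic": ["n_mqtls", "fold_reduction", "mean_initial_ci_cm", "mean_mqtl_ci_cm"],
            "value": [
                len(mqtls),
                round(overall, 2) if overall == overall else float("nan"),
                round(float(np.mean([p.ci_width_cm for p in projected if p.projected])), 2)
                if any(p.projected for p in projected)
                else float("nan"),
                round(float(np.mean([m.ci_width_cm for m in mqtls])), 2) if mqtls else float("nan"),
            ],
        }
    )
    tallies = pd.Series([m.n_stress_classes for m in mqtls], dtype=int).value_counts().sort_index()
    out["mast_tally"] = pd.DataFrame(
        {"n_stress_classes": tallies.index, "n_mqtls": tallies.values}
    )
    if anchored:
        widths = [anchored[m.name].width_bp for m in mqtls if m.name in anchored]
        n = len(widths)
        under20 = int(sum(w < 20_000_000 for w in widths))
        out["physical"] = pd.DataFrame(
            {
                "statistic": ["n_anchored", "n_under_20mb", "pct_under_20mb"],
                "value": [n, under20, percentage(under20, n)],
            }
        )
    return out


# ---------------------------------------------------------------------------
# Run configuration and the staged driver
# ---------------------------------------------------------------------------

STAGES = (
    "read",
    "prepare",
    "consensus",
    "project",
    "meta",
    "anchor",
    "colocalize",
    "mine",
    "deg",
    "promoters",
    "ortho",
    "summarize",
)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    ``qtl_table`` and at least one entry in ``maps`` are required; later
    stages are skipped when their inputs are absent. ``maps`` maps study_id
    to a map TSV (a glob ``map_*.tsv`` in ``indir`` is also accepted via
    :meth:`from_directory`). The MAST thresholds default to the published
    selection rule (>= 5 stress classes, >= 9 member QTLs).
    """

    qtl_table: str
    maps: dict
    base_map: str | None = None
    marker_physical: str | None = None
    mtas: str | None = None
    known_genes: str | None = None
    gene_annotation: str | None = None
    expression: list = field(default_factory=list)  # [(matrix, metadata), ...]
    genome: str | None = None
    motif_table: str | None = None
    ortho_links: str | None = None
    foreign_mqtls: str | None = None
    outdir: str = "mastqtl_out"
    seed: int = 0
    max_ratio: float = 5.0
    max_ci_cm: float = 50.0
    k_max: int = 10
    em_restarts: int = 5
    assign_threshold: float = 0.5
    min_stress_classes: int = 5
    min_members: int = 9
    lfc_threshold: float = 1.0
    min_datasets: int = 3
    min_ortho_genes: int = 1
    mta_window_bp: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    @classmethod
    def from_directory(cls, indir, outdir=None, **overrides) -> "RunConfig":
        """Build a config from the standard layout written by ``simulate``."""

        def maybe(name):
            p = os.path.join(indir, name)
            return p if os.path.exists(p) else None

        maps = {}
        for p in sorted(_glob.glob(os.path.join(indir, "map_*.tsv"))):
            sid = os.path.basename(p)[len("map_") : -len(".tsv")]
            maps[sid] = p
        expression = []
        for p in sorted(_glob.glob(os.path.join(indir, "expr_*.tsv"))):
            if p.endswith("_meta.tsv"):
                continue
            meta = p[: -len(".tsv")] + "_meta.tsv"
            if os.path.exists(meta):
                expression.append([p, meta])
        return cls(
            qtl_table=os.path.join(indir, "qtls.tsv"),
            maps=maps,
            base_map=maybe("base_map.tsv"),
            marker_physical=maybe("marker_physical.tsv"),
            mtas=maybe("mtas.tsv"),
            known_genes=maybe("known_genes.tsv"),
            gene_annotation=maybe("genes.gff3"),
            expression=expression,
            genome=maybe("genome.fasta"),
            ortho_links=maybe("ortho_links.tsv"),
            foreign_mqtls=maybe("foreign_mqtls.tsv"),
            outdir=outdir or os.path.join(indir, "out"),
            **overrides,
        )

    def validate(self) -> None:
        missing = []
        for p in [self.qtl_table, *self.maps.values()]:
            if p and not os.path.exists(p):
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _write(df: pd.DataFrame, outdir: str, name: str) -> str:
    path = os.path.join(outdir, name)
    df.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(cfg: RunConfig, stop_after: str = "summarize") -> dict:
    """Execute the staged analysis; returns {artifact name: object}.

    Every stage writes its TSV artifact into ``cfg.outdir``; the run log
    (attrition accounting and the serialized config) is written as
    ``run_log.json``. ``stop_after`` truncates the stage list (used by the
    per-stage CLI subcommands).
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    stages = STAGES[: STAGES.index(stop_after) + 1]
    log: dict = {"config": {k: v for k, v in asdict(cfg).items()}, "counts": {}, "stages": list(stages)}
    art: dict = {}
    rng = np.random.default_rng(cfg.seed)

    # read + prepare
    records, rejects = qtl_data.read_qtl_table(cfg.qtl_table)
    maps = {sid: consensus_map.GeneticMap.from_tsv(p, sid) for sid, p in cfg.maps.items()}
    if cfg.base_map:
        base = consensus_map.GeneticMap.from_tsv(cfg.base_map, "base")
        all_maps = [base, *maps.values()]
    else:
        all_maps = list(maps.values())
    rejects.to_csv(os.path.join(cfg.outdir, "rejects.tsv"), sep="\t", index=False)
    log["counts"]["collected"] = len(records) + len(rejects)
    log["counts"]["valid"] = len(records)
    log["counts"]["rejected_rows"] = len(rejects)
    art["records"], art["rejects"] = records, rejects
    if "prepare" in stages:
        records = qtl_data.prepare_records(records, maps)
        art["records"] = records
        log["counts"]["complete_after_imputation"] = sum(r.complete for r in records)
        qtl_data.write_qtl_table(records, os.path.join(cfg.outdir, "qtls_prepared.tsv"))
    if "consensus" in stages:
        cmap = consensus_map.build_consensus(all_maps)
        cmap.to_tsv(os.path.join(cfg.outdir, "consensus_map.tsv"))
        cmap.unplaced.to_csv(os.path.join(cfg.outdir, "unplaced_markers.tsv"), sep="\t", index=False)
        art["consensus"] = cmap
        log["counts"]["consensus_markers"] = len(cmap.entries)
    if "project" in stages:
        pcfg = projection.ProjectionConfig(max_ratio=cfg.max_ratio, max_ci_cm=cfg.max_ci_cm)
        projected, report = projection.project_all(records, maps, art["consensus"], pcfg)
        projection.projected_to_frame(projected).to_csv(
            os.path.join(cfg.outdir, "projected.tsv"), sep="\t", index=False
        )
        art["projected"] = projected
        log["counts"]["projection"] = report
    if "meta" in stages:
        mqtls = []
        discards: dict = {}
        for chrom in sorted({p.consensus_chromosome for p in art["projected"] if p.projected}):
            res = meta_analysis.analyze_chromosome(
                art["projected"],
                chrom,
                k_max=cfg.k_max,
                seeds=cfg.em_restarts,
                rng=rng,
                assign_threshold=cfg.assign_threshold,
            )
            mqtls.extend(res["mqtls"])
            discards[chrom] = {k: v for k, v in res["discards"].items() if v}
            res["criteria"].reset_index().to_csv(
                os.path.join(cfg.outdir, f"criteria_{chrom}.tsv"), sep="\t", index=False
            )
        meta_analysis.mqtls_to_frame(mqtls).to_csv(
            os.path.join(cfg.outdir, "mqtls.tsv"), sep="\t", index=False
        )
        art["mqtls"] = mqtls
        log["counts"]["n_mqtls"] = len(mqtls)
        log["counts"]["discards"] = discards
    if "anchor" in stages and cfg.marker_physical:
        phys = physical_anchor.MarkerPhysicalTable.from_tsv(cfg.marker_physical)
        anchored, misses = physical_anchor.anchor_all(art["mqtls"], art["consensus"], phys)
        physical_anchor.to_bed(art["mqtls"], anchored, os.path.join(cfg.outdir, "mqtls.bed"))
        rows = [
            {
                "name": n,
                "chromosome": iv.chromosome,
                "start_bp": iv.start_bp,
                "end_bp": iv.end_bp,
                "peak_bp": iv.peak_bp,
                "flags": ";".join(iv.flags),
            }
            for n, iv in anchored.items()
        ]
        _write(pd.DataFrame(rows), cfg.outdir, "mqtl_physical.tsv")
        art["anchored"], art["unanchored"] = anchored, misses
        log["counts"]["n_anchored"] = len(anchored)
    if "colocalize" in stages and cfg.mtas and "anchored" in art:
        mtas = colocalization.read_mta_table(cfg.mtas)
        mta_report, unresolved = colocalization.overlap_mtas(
            art["anchored"], mtas, window=cfg.mta_window_bp
        )
        _write(mta_report, cfg.outdir, "mta_overlap.tsv")
        art["mta_report"] = mta_report
        log["counts"]["gwas_validated"] = int(mta_report["validated"].sum())
        log["counts"]["gwas_validated_pct"] = percentage(
            int(mta_report["validated"].sum()), len(mta_report)
        )
        if cfg.known_genes:
            genes = colocalization.read_known_genes(cfg.known_genes)
            kg = colocalization.overlap_known_genes(art["anchored"], genes)
            _write(kg, cfg.outdir, "known_gene_overlap.tsv")
            art["known_gene_overlap"] = kg
    if "mine" in stages and cfg.gene_annotation and "anchored" in art:
        annotation = candidate_genes.read_gene_models(cfg.gene_annotation)
        mast = candidate_genes.select_mast_mqtls(
            art["mqtls"], cfg.min_stress_classes, cfg.min_members
        )
        genes_by_mqtl: dict[str, list] = {}
        rows = []
        for m in mast:
            iv = art["anchored"].get(m.name)
            if iv is None:
                continue
            window = candidate_genes.gene_window(iv)
            mined = candidate_genes.mine_genes(window, annotation)
            genes_by_mqtl[m.name] = [g.gene_id for g in mined]
            for g in mined:
                rows.append({"name": m.name, "gene_id": g.gene_id, "start_bp": g.start_bp})
        _write(pd.DataFrame(rows, columns=["name", "gene_id", "start_bp"]), cfg.outdir, "mqtl_genes.tsv")
        art["mast"], art["genes_by_mqtl"], art["annotation"] = mast, genes_by_mqtl, annotation
        log["counts"]["n_mast_selected"] = len(mast)
        log["counts"]["n_genes_mined"] = len({r["gene_id"] for r in rows})
    if "deg" in stages and cfg.expression and "genes_by_mqtl" in art:
        all_genes = sorted({g for gs in art["genes_by_mqtl"].values() for g in gs})
        calls = []
        for i, (mpath, metapath) in enumerate(cfg.expression, start=1):
            ds = candidate_genes.ExpressionDataset.from_tsv(
                mpath, metapath, dataset_id=f"dataset{i}"
            )
            c, _missing = candidate_genes.call_degs(all_genes, ds, cfg.lfc_threshold)
            calls.extend(c)
        ranked = candidate_genes.rank_candidates(calls, cfg.min_datasets)
        _write(ranked, cfg.outdir, "candidates.tsv")
        _write(
            pd.DataFrame(
                [
                    {
                        "gene_id": c.gene_id,
                        "dataset_id": c.dataset_id,
                        "condition": c.condition,
                        "log2fc": c.log2fc,
                        "direction": c.direction,
                    }
                    for c in calls
                ]
            ),
            cfg.outdir,
            "deg_calls.tsv",
        )
        art["deg_calls"], art["candidates"] = calls, ranked
        log["counts"]["n_degs"] = int(ranked["gene_id"].nunique()) if len(ranked) else 0
        log["counts"]["n_promising"] = int(ranked["promising"].sum()) if len(ranked) else 0
    if "promoters" in stages and cfg.genome and "genes_by_mqtl" in art:
        genome = promoter_cre.read_genome_fasta(cfg.genome)
        motifs = promoter_cre.load_motif_table(cfg.motif_table)
        mined_ids = {g for gs in art["genes_by_mqtl"].values() for g in gs}
        gene_models = [g for g in art["annotation"] if g.gene_id in mined_ids]
        promoters, skipped = promoter_cre.extract_promoters(gene_models, genome)
        hits = promoter_cre.scan_promoters(promoters, motifs)
        promoter_cre.hits_to_frame(hits).to_csv(
            os.path.join(cfg.outdir, "promoter_hits.tsv"), sep="\t", index=False
        )
        per_gene, totals = promoter_cre.categorize_cres(hits, motifs)
        per_gene.reset_index().to_csv(
            os.path.join(cfg.outdir, "cre_categories.tsv"), sep="\t", index=False
        )
        art["promoter_hits"], art["cre_categories"] = hits, (per_gene, totals)
        log["counts"]["n_promoter_hits"] = len(hits)
    if "ortho" in stages and cfg.ortho_links and cfg.foreign_mqtls and "genes_by_mqtl" in art:
        links_in = ortho_mqtl.read_ortho_table(cfg.ortho_links)
        foreign = ortho_mqtl.read_foreign_mqtls(cfg.foreign_mqtls)
        links, unmapped = ortho_mqtl.map_orthologues(art["genes_by_mqtl"], links_in)
        pairs = ortho_mqtl.detect_ortho_mqtls(links, foreign, cfg.min_ortho_genes)
        _write(pairs, cfg.outdir, "ortho_pairs.tsv")
        art["ortho_pairs"] = pairs
        log["counts"]["n_ortho_pairs"] = len(pairs)
    if "summarize" in stages:
        summaries = summarize_inputs(art["records"], art.get("consensus"))
        if "mqtls" in art:
            summaries.update(
                {
                    f"mqtl_{k}": v
                    for k, v in summarize_mqtls(
                        art["mqtls"], art["projected"], art.get("anchored")
                    ).items()
                }
            )
        for name, df in summaries.items():
            _write(df, cfg.outdir, f"summary_{name}.tsv")
        art["summaries"] = summaries

    with open(os.path.join(cfg.outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    art["log"] = log
    return art


def hash_artifacts(outdir: str) -> dict:
    """sha256 of every TSV/BED/JSON artifact (reproducibility checks)."""
    out = {}
    for p in sorted(_glob.glob(os.path.join(outdir, "*"))):
        if p.endswith((".tsv", ".bed", ".json")):
            with open(p, "rb") as fh:
                out[os.path.basename(p)] = hashlib.sha256(fh.read()).hexdigest()
    return out
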