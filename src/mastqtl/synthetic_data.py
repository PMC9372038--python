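"""Synthetic study and omics data with known ground truth.

The generator emulates the structure of a curated meta-QTL literature
collection: several mapping studies each report QTLs scattered (with
population-size- and PVE-dependent precision) around a small set of true
MQTL positions; each study has its own linkage map sharing anchor markers
with a dense base map, with per-study cM jitter; a configurable fraction of
records lack LOD/PVE/CI/peak to exercise the imputation rules. Downstream
truth is planted the same way: GWAS MTAs cluster near true MQTL physical
positions, genes are tiled along chromosomes with known candidates inside
the true windows, expression matrices carry planted fold changes, promoters
carry planted cis-element motifs, and orthologue tables place selected genes
inside published foreign (rice/maize) MQTL intervals.

Everything is deterministic under the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .candidate_genes import GeneModel, write_gff3
from .consensus_map import GeneticMap
from .qtl_data import QTLRecord, CIEstimationConfig

# stress label pools per true MQTL (labels, not expanded classes); every pool
# covers at least five of the six stress classes once D+H expands to DS+HS,
# mirroring the MAST loci the published selection rule targets
DEFAULT_STRESS_POOLS = (
    ("DS", "HS", "D+H", "SS", "PHS", "AS"),
    ("DS", "PHS", "AS", "WS", "SS", "HS"),
    ("DS", "HS", "D+H", "SS", "WS", "PHS", "AS"),
    ("SS", "WS", "AS", "D+H"),
    ("D+H", "PHS", "AS", "SS", "WS"),
    ("HS", "SS", "PHS", "WS", "DS"),
)


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    cm_length: float = 150.0
    bp_length: int = 2_000_000


@dataclass(frozen=True)
class TrueMQTL:
    true_id: str
    chromosome: str
    position_cm: float
    stresses: tuple


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    population_type: str
    population_size: int
    n_qtls: int


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of the synthetic study; defaults give the standard scenario

    (3 chromosomes, 8 studies, 200 QTLs around 6 true MQTLs with K = 2/3/1
    per chromosome) which runs the whole pipeline in well under a minute.
    """

    seed: int = 0
    chromosomes: tuple = (
        ChromosomeSpec("1A"),
        ChromosomeSpec("2B"),
        ChromosomeSpec("3D"),
    )
    true_mqtls: tuple = ()
    studies: tuple = ()
    n_base_markers: int = 61
    anchor_fraction: float = 0.7
    n_private_markers: int = 10
    map_jitter_sd_cm: float = 0.5
    peak_scatter_sd_cm: float | None = None  # None: implied by the CI equation
    missing_lod_frac: float = 0.2
    missing_pve_frac: float = 0.2
    missing_ci_frac: float = 0.5
    missing_peak_frac: float = 0.05
    pve_range: tuple = (8.0, 25.0)
    lod_range: tuple = (2.5, 12.0)
    ci_config: CIEstimationConfig = field(default_factory=CIEstimationConfig)
    # omics
    mta_per_mqtl: int = 3
    mta_window_bp: int = 10_000
    mta_background_per_chromosome: int = 0
    gene_spacing_bp: int = 10_000
    gene_length_bp: int = 3_000
    genes_per_locus: int = 2          # dedicated candidate genes at each true locus
    candidate_gene_length_bp: int = 6_000
    n_promising_genes: int = 11
    n_decoy_deg_genes: int = 6
    n_datasets: int = 4
    promising_in_datasets: int = 3
    planted_log2fc: float = 2.5
    decoy_log2fc: float = 1.6
    expression_noise_sd: float = 0.05
    planted_motifs: tuple = ("ABRE", "MBS", "ARE")
    n_conserved_mqtls: int = 2

    def __post_init__(self):
        if not (0 < self.anchor_fraction <= 1):
            raise ValueError("anchor_fraction must be in (0, 1]")
        if not self.true_mqtls:
            object.__setattr__(self, "true_mqtls", _default_true_mqtls(self.chromosomes))
        if not self.studies:
            object.__setattr__(self, "studies", _default_studies())

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


def _default_true_mqtls(chromosomes) -> tuple:
    # K = 2, 3, 1 components on the three default chromosomes
    layout = {0: (40.0, 110.0), 1: (30.0, 75.0, 120.0), 2: (70.0,)}
    out = []
    pool_i = 0
    for ci, chrom in enumerate(chromosomes):
        positions = layout.get(ci % 3, (chrom.cm_length / 2,))
        for j, pos in enumerate(positions, start=1):
            out.append(
                TrueMQTL(
                    true_id=f"T{chrom.name}.{j}",
                    chromosome=chrom.name,
                    position_cm=min(pos, chrom.cm_length),
                    stresses=DEFAULT_STRESS_POOLS[pool_i % len(DEFAULT_STRESS_POOLS)],
                )
            )
            pool_i += 1
    return tuple(out)


def _default_studies() -> tuple:
    types = ("RIL", "DH", "F2", "BC")
    sizes = {"RIL": 220, "DH": 180, "F2": 420, "BC": 320}
    return tuple(
        StudySpec(
            study_id=f"study{i + 1:02d}",
            population_type=types[i % 4],
            population_size=sizes[types[i % 4]] + 10 * (i // 4),
            n_qtls=25,
        )
        for i in range(8)
    )


@dataclass
class SyntheticStudyData:
    base_map: GeneticMap
    study_maps: dict            # study_id -> GeneticMap
    qtls: list                  # QTLRecord (possibly with missing fields)
    marker_physical: pd.DataFrame  # marker, chromosome, bp
    truth_mqtls: pd.DataFrame   # true_id, chromosome, position_cm, position_bp, stresses
    truth_assignments: pd.DataFrame  # qtl_id, true_id, true_position_cm


def _cm_to_bp(cm: float, spec: ChromosomeSpec) -> int:
    frac = min(max(cm / spec.cm_length, 0.0), 1.0)
    return int(round(1 + frac * (spec.bp_length - 1)))


def _repair_order(markers: list, positions: np.ndarray) -> list:
    """Re-sort jittered positions; marker order (by original cM) is kept."""
    return list(zip(markers, np.sort(positions)))


def simulate_studies(scenario: SimulationScenario) -> SyntheticStudyData:
    rng = np.random.default_rng(scenario.seed)
    base_rows = []
    phys_rows = []
    base_positions: dict = {}
    for chrom in scenario.chromosomes:
        pos = np.linspace(0.0, chrom.cm_length, scenario.n_base_markers)
        for i, p in enumerate(pos):
            mk = f"{chrom.name}_M{i:03d}"
            base_rows.append({"chromosome": chrom.name, "marker": mk, "cm": float(p)})
            phys_rows.append(
                {"marker": mk, "chromosome": chrom.name, "bp": _cm_to_bp(p, chrom)}
            )
            base_positions.setdefault(chrom.name, {})[mk] = float(p)
    base_map = GeneticMap("base", pd.DataFrame(base_rows))

    n_anchor = max(2, int(round(scenario.anchor_fraction * scenario.n_base_markers)))
    if n_anchor > scenario.n_base_markers:
        raise ValueError("more anchors requested than base markers")

    study_maps = {}
    study_anchor_maps = {}  # study -> chrom -> (base_pos array, study_pos array)
    for study in scenario.studies:
        rows = []
        study_anchor_maps[study.study_id] = {}
        for chrom in scenario.chromosomes:
            markers = sorted(base_positions[chrom.name], key=base_positions[chrom.name].get)
            # anchors always include the chromosome ends so QTLs stay in span
            inner = rng.choice(
                np.arange(1, len(markers) - 1), size=max(0, n_anchor - 2), replace=False
            )
            idx = sorted({0, len(markers) - 1, *inner.tolist()})
            anchors = [markers[i] for i in idx]
            apos = np.array([base_positions[chrom.name][m] for m in anchors])
            names = list(anchors)
            src = apos.copy()
            for j in range(scenario.n_private_markers):
                names.append(f"{chrom.name}_{study.study_id}_P{j:02d}")
                src = np.append(src, rng.uniform(0.0, chrom.cm_length))
            order = np.argsort(src, kind="stable")
            names = [names[i] for i in order]
            src = src[order]
            jit = src + rng.normal(0.0, scenario.map_jitter_sd_cm, size=len(src))
            jit = np.sort(jit)  # order repair: positions re-sorted, order kept
            jit = jit - min(0.0, jit.min())
            for mk, p in zip(names, jit):
                rows.append({"chromosome": chrom.name, "marker": mk, "cm": float(p)})
            a_study = np.array([jit[names.index(m)] for m in anchors])
            study_anchor_maps[study.study_id][chrom.name] = (apos, a_study)
        study_maps[study.study_id] = GeneticMap(study.study_id, pd.DataFrame(rows))

    # QTL records around the true positions
    qtls: list[QTLRecord] = []
    assign_rows = []
    true_list = list(scenario.true_mqtls)
    for study in scenario.studies:
        k = scenario.ci_config.constant(study.population_type)
        for qi in range(study.n_qtls):
            t = true_list[int(rng.integers(len(true_list)))]
            chrom = scenario.chromosome(t.chromosome)
            pve = float(rng.uniform(*scenario.pve_range))
            ci_width = k / (study.population_size * (pve / 100.0))
            sigma = (
                scenario.peak_scatter_sd_cm
                if scenario.peak_scatter_sd_cm is not None
                else ci_width / 3.92
            )
            peak_base = float(
                np.clip(t.position_cm + rng.normal(0.0, sigma), 0.0, chrom.cm_length)
            )
            ab, asld = study_anchor_maps[study.study_id][t.chromosome]
            peak = float(np.interp(peak_base, ab, asld))
            lo = max(0.0, peak - ci_width / 2.0)
            hi = peak + ci_width / 2.0
            spos = study_maps[study.study_id].positions(t.chromosome)
            mks = sorted(spos, key=spos.get)
            ps = np.array([spos[m] for m in mks])
            li = int(np.searchsorted(ps, peak, side="right")) - 1
            left = mks[max(0, li)]
            right = mks[min(len(mks) - 1, li + 1)]
            lod = float(rng.uniform(*scenario.lod_range))
            qtl_id = f"{study.study_id}_q{qi:03d}"
            # exercise the imputation path on a configurable fraction
            miss_lod = rng.random() < scenario.missing_lod_frac
            miss_pve = rng.random() < scenario.missing_pve_frac
            miss_ci = rng.random() < scenario.missing_ci_frac
            miss_peak = rng.random() < scenario.missing_peak_frac
            qtls.append(
                QTLRecord(
                    qtl_id=qtl_id,
                    study_id=study.study_id,
                    population_type=study.population_type,
                    population_size=study.population_size,
                    stress=t.stresses[int(rng.integers(len(t.stresses)))],
                    trait="MAST",
                    chromosome=t.chromosome,
                    left_marker=left,
                    right_marker=right,
                    peak_cm=None if miss_peak else peak,
                    ci_start_cm=None if (miss_ci or miss_peak) else lo,
                    ci_end_cm=None if (miss_ci or miss_peak) else hi,
                    lod=None if miss_lod else lod,
                    pve=None if miss_pve else pve,
                )
            )
            assign_rows.append(
                {"qtl_id": qtl_id, "true_id": t.true_id, "true_position_cm": t.position_cm}
            )

    truth = pd.DataFrame(
        [
            {
                "true_id": t.true_id,
                "chromosome": t.chromosome,
                "position_cm": t.position_cm,
                "position_bp": _cm_to_bp(t.position_cm, scenario.chromosome(t.chromosome)),
                "stresses": ",".join(t.stresses),
            }
            for t in scenario.true_mqtls
        ]
    )
    return SyntheticStudyData(
        base_map=base_map,
        study_maps=study_maps,
        qtls=qtls,
        marker_physical=pd.DataFrame(phys_rows),
        truth_mqtls=truth,
        truth_assignments=pd.DataFrame(assign_rows),
    )


# ---------------------------------------------------------------------------
# Omics layers
# ---------------------------------------------------------------------------


@dataclass
class SyntheticOmicsData:
    mtas: pd.DataFrame
    genes: list                      # GeneModel
    expression: list                 # ExpressionDataset
    genome: dict                     # chromosome -> sequence
    ortho_links: pd.DataFrame
    foreign_mqtls: pd.DataFrame
    truth_promising: tuple           # gene ids planted as cross-dataset DEGs
    truth_decoys: tuple
    truth_motifs: dict               # gene_id -> tuple of planted motif names
    truth_ortho_pairs: pd.DataFrame  # true_id, species, foreign_mqtl


def simulate_omics(
    scenario: SimulationScenario, study_data: SyntheticStudyData
) -> SyntheticOmicsData:
    from .candidate_genes import ExpressionDataset
    from .promoter_cre import load_motif_table

    rng = np.random.default_rng(scenario.seed + 1)
    truth = study_data.truth_mqtls

    # --- GWAS MTAs clustered around the true physical positions
    mta_rows = []
    for t in truth.to_dict("records"):
        spec = scenario.chromosome(t["chromosome"])
        for j in range(scenario.mta_per_mqtl):
            bp = int(
                np.clip(
                    t["position_bp"]
                    + rng.integers(-scenario.mta_window_bp, scenario.mta_window_bp + 1),
                    1,
                    spec.bp_length,
                )
            )
            mta_rows.append(
                {
                    "marker": f"mta_{t['true_id']}_{j}",
                    "chromosome": t["chromosome"],
                    "bp": bp,
                    "stress": str(t["stresses"]).split(",")[0],
                    "study_id": f"gwas{j + 1:02d}",
                }
            )
    for spec in scenario.chromosomes:
        for j in range(scenario.mta_background_per_chromosome):
            mta_rows.append(
                {
                    "marker": f"mta_bg_{spec.name}_{j}",
                    "chromosome": spec.name,
                    "bp": int(rng.integers(1, spec.bp_length + 1)),
                    "stress": "DS",
                    "study_id": "gwas_bg",
                }
            )
    mtas = pd.DataFrame(mta_rows)

    # --- tiled gene models plus a dedicated candidate cluster at each true
    # locus (tandem overlapping genes spanning the true position, so that any
    # physical window containing the locus is guaranteed to mine them)
    genes: list[GeneModel] = []
    for spec in scenario.chromosomes:
        i = 0
        start = 1
        while start + scenario.gene_length_bp <= spec.bp_length:
            genes.append(
                GeneModel(
                    gene_id=f"Gene{spec.name}.{i:04d}",
                    chromosome=spec.name,
                    start_bp=start,
                    end_bp=start + scenario.gene_length_bp - 1,
                    strand="+" if i % 2 == 0 else "-",
                    function="synthetic gene model",
                )
            )
            i += 1
            start += scenario.gene_spacing_bp
    records = truth.to_dict("records")
    cluster_by_true: dict[str, list[GeneModel]] = {}
    half = scenario.candidate_gene_length_bp // 2
    for t in records:
        spec = scenario.chromosome(t["chromosome"])
        cluster = []
        for j in range(scenario.genes_per_locus):
            start = max(1, t["position_bp"] - half + 150 * j)
            end = min(spec.bp_length, start + scenario.candidate_gene_length_bp - 1)
            g = GeneModel(
                gene_id=f"Cand_{t['true_id']}.{j}",
                chromosome=t["chromosome"],
                start_bp=start,
                end_bp=end,
                strand="+",
                function="planted candidate gene",
            )
            cluster.append(g)
            genes.append(g)
        cluster_by_true[t["true_id"]] = cluster
    genes.sort(key=lambda g: (g.chromosome, g.start_bp, g.gene_id))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    # --- planted DEG candidates: the locus clusters, round-robin over loci
    planted: list[str] = []
    rank = 0
    while len(planted) < scenario.n_promising_genes:
        for t in records:
            cluster = cluster_by_true[t["true_id"]]
            if rank < len(cluster) and len(planted) < scenario.n_promising_genes:
                planted.append(cluster[rank].gene_id)
        rank += 1
        if rank > scenario.genes_per_locus:
            raise ValueError("n_promising_genes exceeds planted cluster capacity")
    # decoys: tiled genes near the loci, differentially expressed in only one
    # dataset — mined or not, they must never rank as promising
    decoys: list[str] = []
    ti = 0
    ranks: dict[str, int] = {}
    while len(decoys) < scenario.n_decoy_deg_genes:
        t = records[ti % len(records)]
        pool = [g for g in by_chrom[t["chromosome"]] if not g.gene_id.startswith("Cand_")]
        r = ranks.get(t["true_id"], 0)
        ranks[t["true_id"]] = r + 1
        nearest = sorted(pool, key=lambda g: abs(g.start_bp - t["position_bp"]))
        cand = nearest[r].gene_id
        if cand not in decoys:
            decoys.append(cand)
        ti += 1

    # --- expression datasets with planted fold changes
    datasets = []
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.uniform(2.0, 6.0, size=len(gene_ids))
    promising_sets = {
        g: sorted(
            rng.choice(scenario.n_datasets, size=scenario.promising_in_datasets, replace=False)
        )
        for g in planted
    }
    decoy_sets = {g: [int(rng.integers(scenario.n_datasets))] for g in decoys}
    for d in range(scenario.n_datasets):
        samples = ["control_1", "control_2", "stress_1", "stress_2"]
        mat = pd.DataFrame(
            rng.normal(0.0, scenario.expression_noise_sd, size=(len(gene_ids), 4))
            + baseline[:, None],
            index=pd.Index(gene_ids, name="gene_id"),
            columns=samples,
        )
        for g in planted:
            if d in promising_sets[g]:
                mat.loc[g, ["stress_1", "stress_2"]] += scenario.planted_log2fc
        for g in decoys:
            if d in decoy_sets[g]:
                mat.loc[g, ["stress_1", "stress_2"]] += scenario.decoy_log2fc
        meta = pd.DataFrame(
            {
                "sample": samples,
                "condition": ["control", "control", "stress", "stress"],
                "is_control": [True, True, False, False],
            }
        )
        datasets.append(
            ExpressionDataset(dataset_id=f"dataset{d + 1}", matrix=mat, metadata=meta)
        )

    # --- genome with planted promoter motifs for the planted genes
    motif_by_name = {m.name: m for m in load_motif_table()}
    genome: dict[str, np.ndarray] = {}
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    for spec in scenario.chromosomes:
        genome[spec.name] = rng.choice(alphabet, size=spec.bp_length).copy()
    gene_of = {g.gene_id: g for g in genes}
    truth_motifs: dict[str, tuple] = {}
    from Bio.Seq import Seq

    for gid in planted:
        g = gene_of[gid]
        seq = genome[g.chromosome]
        names = []
        for mi, mname in enumerate(scenario.planted_motifs):
            pat = motif_by_name[mname].pattern  # planted motifs use ACGT-only patterns
            offset = 300 + 200 * mi  # bases upstream of ATG
            if g.strand == "+":
                pos0 = g.start_bp - 1 - offset  # 0-based start of pattern
                if pos0 < 0:
                    continue
                seq[pos0 : pos0 + len(pat)] = np.frombuffer(pat.encode(), dtype="S1")
            else:
                rc = str(Seq(pat).reverse_complement())
                end0 = g.end_bp + offset  # pattern ends this many bases downstream
                if end0 + len(rc) > len(seq):
                    continue
                seq[end0 : end0 + len(rc)] = np.frombuffer(rc.encode(), dtype="S1")
            names.append(mname)
        truth_motifs[gid] = tuple(names)
    genome_str = {c: s.tobytes().decode() for c, s in genome.items()}

    # --- orthologues planted inside foreign MQTL intervals
    foreign = pd.DataFrame(
        [
            {
                "species": "rice",
                "label": "rMQTL1",
                "chromosome": "1",
                "start_bp": 1_000_000,
                "end_bp": 2_000_000,
                "stress": "DS",
            },
            {
                "species": "maize",
                "label": "mMQTL1",
                "chromosome": "2",
                "start_bp": 5_000_000,
                "end_bp": 6_000_000,
                "stress": "DS",
            },
        ]
    )
    # conserved loci: the first true locus on each chromosome (one per
    # chromosome, so mined windows can never cross-talk between them)
    conserved = []
    seen_chroms: set = set()
    for t in records:
        if t["chromosome"] not in seen_chroms:
            conserved.append(t)
            seen_chroms.add(t["chromosome"])
        if len(conserved) == scenario.n_conserved_mqtls:
            break
    link_rows = []
    pair_rows = []
    for ci, t in enumerate(conserved):
        fm = foreign.iloc[ci % len(foreign)]
        for gi, g in enumerate(cluster_by_true[t["true_id"]]):
            start = int(fm["start_bp"]) + 10_000 * (gi + 1)
            link_rows.append(
                {
                    "wheat_gene": g.gene_id,
                    "species": fm["species"],
                    "foreign_gene": f"{fm['species']}_g{ci}{gi}",
                    "foreign_chromosome": fm["chromosome"],
                    "foreign_start_bp": start,
                    "foreign_end_bp": start + 3_000,
                }
            )
        pair_rows.append(
            {"true_id": t["true_id"], "species": fm["species"], "foreign_mqtl": fm["label"]}
        )
    # one orthologue outside every interval: must never create a pair
    outsider = by_chrom[records[-1]["chromosome"]][0]
    link_rows.append(
        {
            "wheat_gene": outsider.gene_id,
            "species": "rice",
            "foreign_gene": "rice_outside",
            "foreign_chromosome": "1",
            "foreign_start_bp": 5_000_000,
            "foreign_end_bp": 5_003_000,
        }
    )
    return SyntheticOmicsData(
        mtas=mtas,
        genes=genes,
        expression=datasets,
        genome=genome_str,
        ortho_links=pd.DataFrame(link_rows),
        foreign_mqtls=foreign,
        truth_promising=tuple(planted),
        truth_decoys=tuple(decoys),
        truth_motifs=truth_motifs,
        truth_ortho_pairs=pd.DataFrame(pair_rows),
    )


def match_mqtls_to_truth(mqtls: Sequence, truth: pd.DataFrame) -> pd.DataFrame:
    """Match each true MQTL to the nearest detected MQTL on its chromosome.

    Returns (true_id, chromosome, true_position_cm, detected, detected_position_cm,
    abs_error_cm); ``detected`` is None when the chromosome has no MQTL.
    """
    rows = []
    for t in truth.to_dict("records"):
        cands = [m for m in mqtls if m.chromosome == t["chromosome"]]
        if not cands:
            rows.append(
                {
                    "true_id": t["true_id"],
                    "chromosome": t["chromosome"],
                    "true_position_cm": t["position_cm"],
                    "detected": None,
                    "detected_position_cm": float("nan"),
                    "abs_error_cm": float("inf"),
                }
            )
            continue
        best = min(cands, key=lambda m: abs(m.position_cm - t["position_cm"]))
        rows.append(
            {
                "true_id": t["true_id"],
                "chromosome": t["chromosome"],
                "true_position_cm": t["position_cm"],
                "detected": best.name,
                "detected_position_cm": best.position_cm,
                "abs_error_cm": abs(best.position_cm - t["position_cm"]),
            }
        )
    return pd.DataFrame(rows)


def write_inputs(
    scenario: SimulationScenario,
    study_data: SyntheticStudyData,
    omics: SyntheticOmicsData | None,
    outdir,
) -> dict:
    """Write every standard input file the pipeline readers consume.

    Returns {logical name: path}. Deterministic file contents under seed.
    """
    import os

    from .qtl_data import write_qtl_table

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    study_data.base_map.to_tsv(p("base_map.tsv"))
    for sid, smap in study_data.study_maps.items():
        smap.to_tsv(p(f"map_{sid}.tsv"))
    write_qtl_table(study_data.qtls, p("qtls.tsv"))
    study_data.marker_physical.to_csv(p("marker_physical.tsv"), sep="\t", index=False)
    study_data.truth_mqtls.to_csv(p("truth_mqtls.tsv"), sep="\t", index=False)
    study_data.truth_assignments.to_csv(p("truth_assignments.tsv"), sep="\t", index=False)
    if omics is not None:
        omics.mtas.to_csv(p("mtas.tsv"), sep="\t", index=False)
        write_gff3(omics.genes, p("genes.gff3"))
        for ds in omics.expression:
            ds.matrix.to_csv(p(f"expr_{ds.dataset_id}.tsv"), sep="\t")
            ds.metadata.to_csv(p(f"expr_{ds.dataset_id}_meta.tsv"), sep="\t", index=False)
        with open(p("genome.fasta"), "w") as fh:
            for chrom in sorted(omics.genome):
                fh.write(f">{chrom}\n")
                seq = omics.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        omics.ortho_links.to_csv(p("ortho_links.tsv"), sep="\t", index=False)
        omics.foreign_mqtls.to_csv(p("foreign_mqtls.tsv"), sep="\t", index=False)
    return paths
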