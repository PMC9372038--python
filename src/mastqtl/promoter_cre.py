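"""Promoter extraction and cis-regulatory element (CRE) scanning.

Promoters are the 1500 bp immediately upstream of the translational start
(ATG): for a + strand gene, bases [start-1500, start-1]; for a - strand gene,
the reverse complement of [end+1, end+1500] — so the returned sequence always
reads 5'→3' toward the gene. Scanning matches IUPAC consensus strings from a
bundled motif table on the sense strand only; all (possibly overlapping)
exact IUPAC-consistent matches are reported, scored by the number of matched
bases. This deterministic consensus matching stands in for matrix-based CRE
predictors and is adequate for categorical CRE analyses; it is not a PWM
scorer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .candidate_genes import GeneModel

PROMOTER_LENGTH = 1500

CATEGORIES = (
    "growth_development",
    "stress_responsiveness",
    "phytohormone_responsiveness",
    "core_promoter",
    "uncharacterized",
)

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str  # IUPAC nucleotide consensus
    category: str

    def __post_init__(self):
        if not self.pattern or any(c not in IUPAC for c in self.pattern.upper()):
            raise ValueError(f"{self.name}: pattern must be non-empty IUPAC")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")

    def regex(self) -> re.Pattern:
        return re.compile("".join(IUPAC[c] for c in self.pattern.upper()))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    offset: int           # 1-based within the promoter (1 = 5'-most base)
    offset_from_atg: int  # negative; -1 = base immediately before ATG
    matched: str
    score: int            # matched bases (= pattern length)


def load_motif_table(path=None) -> list[MotifDef]:
    """Bundled CRE consensus table, or a user TSV (name, pattern, category)."""
    if path is None:
        src = resources.files("mastqtl.data").joinpath("motifs.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [MotifDef(r["name"], r["pattern"], r["category"]) for r in df.to_dict("records")]


def read_genome_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_promoters(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    length: int = PROMOTER_LENGTH,
) -> tuple[dict, list[str]]:
    """gene_id -> (promoter sequence, truncated flag); plus skipped genes.

    Promoters shorter than ``length`` (gene near a chromosome end) are
    returned truncated with the flag set; genes on chromosomes absent from
    the genome are skipped and listed.
    """
    out: dict[str, tuple[str, bool]] = {}
    skipped: list[str] = []
    for g in genes:
        seq = genome.get(g.chromosome)
        if seq is None:
            skipped.append(g.gene_id)
            continue
        L = len(seq)
        if g.strand == "+":
            start = max(1, g.start_bp - length)
            end = g.start_bp - 1
            prom = seq[start - 1 : end] if end >= start else ""
            truncated = g.start_bp - length < 1
        else:
            start = g.end_bp + 1
            end = min(L, g.end_bp + length)
            raw = seq[start - 1 : end] if end >= start else ""
            prom = str(Seq(raw).reverse_complement())
            truncated = g.end_bp + length > L
        out[g.gene_id] = (prom, truncated)
    return out, skipped


def scan_motifs(
    promoter: str, motifs: Sequence[MotifDef], gene_id: str = ""
) -> list[MotifHit]:
    """All sense-strand IUPAC matches in a promoter, overlapping included."""
    seq = promoter.upper()
    L = len(seq)
    hits: list[MotifHit] = []
    for m in motifs:
        rx = m.regex()
        n = len(m.pattern)
        # lookahead to collect overlapping occurrences
        for match in re.finditer(f"(?=({rx.pattern}))", seq):
            start = match.start()
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    motif=m.name,
                    offset=start + 1,
                    offset_from_atg=start - L,
                    matched=seq[start : start + n],
                    score=n,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.motif))
    return hits


def scan_promoters(
    promoters: Mapping[str, tuple], motifs: Sequence[MotifDef]
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for gene_id in sorted(promoters):
        seq = promoters[gene_id][0] if isinstance(promoters[gene_id], tuple) else promoters[gene_id]
        hits.extend(scan_motifs(seq, motifs, gene_id=gene_id))
    return hits


def categorize_cres(
    hits: Iterable[MotifHit], motifs: Sequence[MotifDef]
) -> tuple[pd.DataFrame, dict]:
    """Per-gene and global hit counts per functional category."""
    cat_of = {m.name: m.category for m in motifs}
    per_gene: dict[str, dict] = {}
    total = {c: 0 for c in CATEGORIES}
    for h in hits:
        cat = cat_of.get(h.motif, "uncharacterized")
        row = per_gene.setdefault(h.gene_id, {c: 0 for c in CATEGORIES})
        row[cat] += 1
        total[cat] += 1
    df = pd.DataFrame.from_dict(per_gene, orient="index").fillna(0).astype(int)
    df.index.name = "gene_id"
    df = df.reindex(columns=list(CATEGORIES), fill_value=0).sort_index()
    return df, total


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "motif": h.motif,
                "offset": h.offset,
                "offset_from_atg": h.offset_from_atg,
                "matched": h.matched,
                "score": h.score,
            }
            for h in hits
        ],
        columns=["gene_id", "motif", "offset", "offset_from_atg", "matched", "score"],
    )
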