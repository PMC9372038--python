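"""Ortho-MQTL detection: conserved MQTL regions across wheat, rice and maize.

Wheat genes mined from MQTL windows are joined to a user-supplied orthologue
table (wheat gene -> rice/maize gene with foreign genomic coordinates). A
(wheat MQTL, foreign MQTL) pair is declared an ortho-MQTL when at least
``min_genes`` orthologues of the wheat MQTL's genes fall inside the foreign
published MQTL interval (any-overlap of the foreign gene span).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ORTHO_COLUMNS = (
    "wheat_gene",
    "species",
    "foreign_gene",
    "foreign_chromosome",
    "foreign_start_bp",
    "foreign_end_bp",
)
FOREIGN_MQTL_COLUMNS = ("species", "label", "chromosome", "start_bp", "end_bp", "stress")


def read_ortho_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_foreign_mqtls(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def map_orthologues(
    genes_by_mqtl: Mapping[str, Sequence[str]], ortho: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Join wheat MQTL genes onto the orthologue table.

    Returns (links frame with an added ``mqtl`` column, {mqtl: n_unmapped}).
    Duplicate wheat->foreign rows are collapsed with a warning.
    """
    dup = ortho.duplicated(subset=["wheat_gene", "species", "foreign_gene"])
    if dup.any():
        logger.warning("collapsing %d duplicate orthologue rows", int(dup.sum()))
        ortho = ortho[~dup]
    rows = []
    unmapped: dict[str, int] = {}
    by_gene = {g: sub for g, sub in ortho.groupby("wheat_gene")}
    for mqtl in sorted(genes_by_mqtl):
        unmapped[mqtl] = 0
        for gene in genes_by_mqtl[mqtl]:
            sub = by_gene.get(gene)
            if sub is None or sub.empty:
                unmapped[mqtl] += 1
                continue
            for r in sub.to_dict("records"):
                rows.append({"mqtl": mqtl, **r})
    links = pd.DataFrame(rows, columns=["mqtl", *ORTHO_COLUMNS])
    return links, unmapped


def detect_ortho_mqtls(
    links: pd.DataFrame, foreign_mqtls: pd.DataFrame, min_genes: int = 1
) -> pd.DataFrame:
    """(wheat MQTL, foreign MQTL) pairs with >= min_genes contained orthologues.

    Containment uses any-overlap between the foreign gene span and the
    foreign MQTL interval on matching species + chromosome.
    """
    rows = []
    for fm in foreign_mqtls.to_dict("records"):
        sub = links[
            (links["species"] == fm["species"])
            & (links["foreign_chromosome"].astype(str) == str(fm["chromosome"]))
        ]
        if sub.empty:
            continue
        inside = sub[
            (sub["foreign_end_bp"] >= int(fm["start_bp"]))
            & (sub["foreign_start_bp"] <= int(fm["end_bp"]))
        ]
        for mqtl, grp in inside.groupby("mqtl"):
            n = grp["wheat_gene"].nunique()
            if n >= min_genes:
                rows.append(
                    {
                        "wheat_mqtl": mqtl,
                        "species": fm["species"],
                        "foreign_mqtl": fm["label"],
                        "n_shared_genes": int(n),
                        "shared_genes": ";".join(sorted(grp["wheat_gene"].unique())),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["wheat_mqtl", "species", "foreign_mqtl", "n_shared_genes", "shared_genes"]
    )
    return df.sort_values(["wheat_mqtl", "species", "foreign_mqtl"]).reset_index(drop=True)
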