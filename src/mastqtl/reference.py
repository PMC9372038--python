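"""Published reference list of wheat MAST MQTLs (bundled data).

The bundled table is the published list of bread-wheat meta-QTLs conferring
tolerance to five or all six abiotic stresses (DS, HS, SS, WS, PHS, AS),
with their genetic CIs, flanking markers, member counts and per-stress QTL
tallies. It is used to exercise and check the stress-class tallying rules:
combined drought+heat records ("D+H") expand into DS and HS, and the
aluminium code is printed "AL" in some rows and normalized to "AS".
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta_analysis import STRESS_CLASSES, expand_stress
from .qtl_data import normalize_stress


def load_mast_reference() -> pd.DataFrame:
    src = resources.files("mastqtl.data").joinpath("mast_reference.tsv")
    with resources.as_file(src) as p:
        return pd.read_csv(p, sep="\t")


def parse_stress_tally(spec: str) -> dict:
    """Parse 'AS:2,D+H:7,...' into an expanded per-class tally.

    Codes are normalized (AL -> AS) and combined D+H counts add to both DS
    and HS, so the result keys are the six stress classes only.
    """
    tally = {c: 0 for c in STRESS_CLASSES}
    for part in str(spec).split(","):
        if not part.strip():
            continue
        code, n = part.rsplit(":", 1)
        for cls in expand_stress(normalize_stress(code)):
            tally[cls] += int(n)
    return tally


def stress_class_counts(df: pd.DataFrame) -> pd.Series:
    """Number of distinct stress classes covered by each reference MQTL."""
    return df["stresses"].map(
        lambda s: sum(1 for v in parse_stress_tally(s).values() if v > 0)
    )
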