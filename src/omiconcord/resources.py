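"""Packaged reference tables.

Ships the curated 24 h kinomic KEGG pathway annotations for the SKOV3 and
OVCAR3 FASN-inhibitor response (pathway id, name, functional system FS1 =
molecular/cellular interaction or FS2 = stress response due to derangement,
and the number of phosphoproteins changed beyond the 150%/50%-of-control
thresholds).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_FILES = {
    "SKOV3": "skov3_kegg_pathways_24h.tsv",
    "OVCAR3": "ovcar3_kegg_pathways_24h.tsv",
}


def load_kinomic_pathway_table(cell_line: str) -> pd.DataFrame:
    """Affected-KEGG-pathway table of one cell line after 24 h of FASN
    inhibition; columns ``pathway_id``, ``pathway_name``,
    ``functional_system`` and ``n_phosphoproteins``."""
    key = cell_line.upper()
    if key not in _FILES:
        raise ValueError(f"unknown cell line {cell_line!r}; expected SKOV3 or OVCAR3")
    ref = resources.files("omiconcord") / "data" / _FILES[key]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def affected_pathways(cell_line: str) -> set[str]:
    """The set of affected pathway ids for one cell line."""
    return set(load_kinomic_pathway_table(cell_line)["pathway_id"])
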