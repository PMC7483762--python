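"""Cross-cell-line concordance: matching scores, process ranking, pathway
status and two-line pathway overlap.

The matching score separates causal drug mechanisms from secondary metabolic
reactions: a protein significantly regulated in the *same* direction at the
*same* timepoint in both cell lines scores 1.0, any other pattern scores
0.0, and each biological (sub-)process is summarised by the arithmetic mean
of its member scores. Processes driven directly by the drug accumulate high
means in both cell lines; cell-context-dependent (secondary) responses score
near the chance level. Phosphoprotein pathways are additionally classified
as ``up`` (all changed members above an upper percent-of-control threshold,
default 150), ``down`` (all below a lower threshold, default 50), ``mixed``
or ``unaffected``, and affected-pathway sets of the two cell lines are
compared by plain set overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .differential import DOWN, UNCHANGED, UP

DIRECTIONS = (UP, DOWN, UNCHANGED)


@dataclass(frozen=True)
class RegulationCall:
    """Directional regulation of one analyte in one cell line at one time."""

    analyte: str
    cell_line: str
    timepoint_h: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def protein_matching_score(call_a: RegulationCall, call_b: RegulationCall) -> float:
    """1.0 iff both cell lines show significant regulation in the same
    direction at the same timepoint; 0.0 otherwise."""
    if call_a.analyte != call_b.analyte:
        raise ValueError(
            f"calls refer to different analytes: {call_a.analyte!r} vs {call_b.analyte!r}"
        )
    if call_a.timepoint_h != call_b.timepoint_h:
        raise ValueError("calls refer to different timepoints")
    if call_a.cell_line == call_b.cell_line:
        raise ValueError("calls must come from two different cell lines")
    same = call_a.direction == call_b.direction != UNCHANGED
    return 1.0 if same else 0.0


def process_matching_score(scores) -> float:
    """Arithmetic mean of individual protein matching scores."""
    scores = list(scores)
    if not scores:
        raise ValueError("cannot average an empty score list")
    return float(np.mean(scores))


def _direction_lookup(calls: pd.DataFrame) -> dict[tuple, str]:
    dup = calls.duplicated(["analyte", "cell_line", "timepoint_h"])
    if dup.any():
        raise ValueError("more than one call per (analyte, cell_line, timepoint)")
    return {
        (r.analyte, r.timepoint_h): r.direction for r in calls.itertuples(index=False)
    }


def matching_table(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    process_map: dict[str, set[str]],
    mode: str = "same_time",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein binary scores and per-process means across two cell lines.

    ``calls_a``/``calls_b`` are differential-call tables (one cell line each,
    columns ``analyte``, ``timepoint_h``, ``direction``). The protein universe
    per timepoint contains every analyte significantly regulated in at least
    one cell line at that timepoint; proteins unchanged in both lines do not
    enter the mean. Analytes may belong to several processes and contribute to
    each. ``mode="any_time"`` relaxes the same-time requirement: a protein
    scores 1.0 if both lines regulate it in the same direction at *any*
    (possibly different) timepoint, evaluated once per protein (timepoint
    column set to "any").

    Returns ``(protein_scores, process_scores)``.
    """
    if mode not in ("same_time", "any_time"):
        raise ValueError(f"unknown mode {mode!r}")
    dir_a = _direction_lookup(calls_a)
    dir_b = _direction_lookup(calls_b)
    timepoints = sorted(
        {t for _, t in dir_a} | {t for _, t in dir_b}
    )
    analytes = sorted({a for a, _ in dir_a} | {a for a, _ in dir_b})

    rows = []
    if mode == "same_time":
        for t in timepoints:
            for a in analytes:
                da = dir_a.get((a, t), UNCHANGED)
                db = dir_b.get((a, t), UNCHANGED)
                if da == db == UNCHANGED:
                    continue
                rows.append((a, t, 1.0 if (da == db != UNCHANGED) else 0.0))
    else:
        for a in analytes:
            da = {dir_a.get((a, t), UNCHANGED) for t in timepoints} - {UNCHANGED}
            db = {dir_b.get((a, t), UNCHANGED) for t in timepoints} - {UNCHANGED}
            if not da and not db:
                continue
            rows.append((a, "any", 1.0 if da & db else 0.0))
    protein_scores = pd.DataFrame(rows, columns=["analyte", "timepoint_h", "score"])

    proc_rows = []
    for t, grp in protein_scores.groupby("timepoint_h"):
        member_scores = dict(zip(grp["analyte"], grp["score"]))
        for process, members in process_map.items():
            hits = [member_scores[a] for a in members if a in member_scores]
            if not hits:
                continue
            proc_rows.append((process, t, float(np.mean(hits)), len(hits)))
    process_scores = pd.DataFrame(
        proc_rows, columns=["process", "timepoint_h", "mean_score", "n_members"]
    )
    return protein_scores, process_scores


def rank_processes(process_scores: pd.DataFrame, timepoint) -> pd.DataFrame:
    """Processes at one timepoint, sorted by mean matching score descending;
    ties break alphabetically."""
    at_t = process_scores.loc[process_scores["timepoint_h"] == timepoint]
    return at_t.sort_values(
        ["mean_score", "process"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def classify_pathway_regulation(
    member_pcts, up_thr: float = 150.0, down_thr: float = 50.0
) -> str:
    """Pathway status from member percent-of-control values: ``up`` if the
    only threshold-crossing members exceed ``up_thr``, ``down`` if they fall
    below ``down_thr``, ``mixed`` if both kinds occur, ``unaffected`` if no
    member crosses either threshold."""
    pcts = np.asarray(list(member_pcts), dtype=float)
    if pcts.size == 0:
        raise ValueError("empty member list")
    has_up = bool((pcts > up_thr).any())
    has_down = bool((pcts < down_thr).any())
    if has_up and has_down:
        return "mixed"
    if has_up:
        return "up"
    if has_down:
        return "down"
    return "unaffected"


class PathwayOverlap(NamedTuple):
    both: int
    only_a: int
    only_b: int


def pathway_overlap(pathways_a, pathways_b) -> PathwayOverlap:
    """Counts of pathways affected in both cell lines or in exactly one."""
    a, b = set(pathways_a), set(pathways_b)
    return PathwayOverlap(len(a & b), len(a - b), len(b - a))


def pathway_status_table(
    phospho_pcts: pd.DataFrame,
    pathway_map: dict[str, set[str]],
    up_thr: float = 150.0,
    down_thr: float = 50.0,
) -> pd.DataFrame:
    """Classify every pathway of one cell line from a phosphoprotein
    percent-of-control table (columns ``analyte``, ``pct_of_control``)."""
    pct = dict(zip(phospho_pcts["analyte"], phospho_pcts["pct_of_control"]))
    rows = []
    for pathway, members in pathway_map.items():
        vals = [pct[a] for a in members if a in pct]
        if not vals:
            continue
        rows.append(
            (pathway, len(vals), classify_pathway_regulation(vals, up_thr, down_thr))
        )
    return pd.DataFrame(rows, columns=["pathway", "n_phosphoproteins", "status"])


def concordance_report(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    process_map: dict[str, set[str]],
    phospho_pcts_a: pd.DataFrame | None = None,
    phospho_pcts_b: pd.DataFrame | None = None,
    pathway_map: dict[str, set[str]] | None = None,
    mode: str = "same_time",
    up_thr: float = 150.0,
    down_thr: float = 50.0,
) -> dict:
    """Full concordance bundle: matching tables, per-timepoint rankings and —
    when phosphoprotein percent tables are supplied — pathway status per cell
    line plus the two-line overlap summary."""
    protein_scores, process_scores = matching_table(calls_a, calls_b, process_map, mode)
    rankings = {
        t: rank_processes(process_scores, t)
        for t in process_scores["timepoint_h"].unique()
    }
    report = {
        "protein_scores": protein_scores,
        "process_scores": process_scores,
        "rankings": rankings,
    }
    if phospho_pcts_a is not None and phospho_pcts_b is not None:
        if pathway_map is None:
            raise ValueError("pathway_map required with phosphoprotein tables")
        status_a = pathway_status_table(phospho_pcts_a, pathway_map, up_thr, down_thr)
        status_b = pathway_status_table(phospho_pcts_b, pathway_map, up_thr, down_thr)
        affected_a = set(status_a.loc[status_a["status"] != "unaffected", "pathway"])
        affected_b = set(status_b.loc[status_b["status"] != "unaffected", "pathway"])
        overlap = pathway_overlap(affected_a, affected_b)
        report |= {
            "pathway_status_a": status_a,
            "pathway_status_b": status_b,
            "overlap": overlap,
        }
    elif (phospho_pcts_a is None) != (phospho_pcts_b is None):
        warnings.warn("phosphoprotein table missing for one cell line; pathway stage skipped")
    return report
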