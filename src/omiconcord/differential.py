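"""Differential calling against vehicle control.

For every (analyte, cell line, timepoint) stratum the drug arm is compared to
the vehicle arm: intensities are expressed in percent of the vehicle-control
mean (control = 100%), significance is assessed with a two-tailed Student
t-test (pooled variance by default, Welch behind a flag) and each analyte is
assigned a direction — ``up`` (p < alpha and > 100% of control), ``down``
(p < alpha and < 100%) or ``unchanged``. Missing values can be imputed from a
down-shifted normal distribution beforehand, mirroring the standard
left-censored proteomics convention.

No multiple-testing correction is applied by default (matching the uncorrected
p < 0.05 scheme the pipeline reproduces); Benjamini-Hochberg is available via
``fdr=True``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import DRUG, VEHICLE, AnalyteMatrix, strata

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


def percent_of_control(treated_reps, control_reps) -> tuple[float, float]:
    """Mean and sample SD of treated replicates in percent of the control mean.

    Each treated replicate is divided by the control-group mean and scaled to
    percent (control = 100). A single treated replicate gets SD 0 by
    convention.
    """
    treated = np.asarray(treated_reps, dtype=float)
    control = np.asarray(control_reps, dtype=float)
    treated = treated[~np.isnan(treated)]
    control = control[~np.isnan(control)]
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups need at least one observed value")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError(f"degenerate control: mean {control_mean} <= 0")
    pct = treated / control_mean * 100.0
    sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
    return float(pct.mean()), sd


def two_tailed_t_test(x, y, pooled: bool = True) -> float:
    """Two-tailed two-sample t-test p-value.

    ``pooled=True`` gives the classical Student test with pooled variance;
    ``pooled=False`` the Welch unequal-variance variant. Two groups with zero
    spread and equal means return p = 1 by convention (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observed values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            warnings.warn("zero variance with equal means; p = 1 by convention")
            return 1.0
        return 0.0
    p = stats.ttest_ind(x, y, equal_var=pooled).pvalue
    return float(p)


def impute_missing(
    matrix: AnalyteMatrix,
    shift_sd: float = 1.8,
    width_sd: float = 0.3,
    seed: int = 0,
) -> AnalyteMatrix:
    """Replace missing cells from a down-shifted normal distribution.

    Per sample column, on the log2 scale: draws come from
    Normal(mean_obs - shift_sd * sd_obs, (width_sd * sd_obs)^2) where mean_obs
    and sd_obs describe that column's observed values. Observed cells are
    untouched; output is deterministic given the seed.
    """
    values = matrix.values.to_numpy(dtype=float, copy=True)
    rng = np.random.default_rng(seed)
    log2 = np.log2(values, out=np.full_like(values, np.nan), where=values > 0)
    log2[np.isnan(values)] = np.nan
    for j in range(values.shape[1]):
        col = log2[:, j]
        miss = np.isnan(values[:, j])
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size < 2:
            raise ValueError(
                f"column {matrix.values.columns[j]!r} has fewer than 2 observed "
                "values; cannot estimate an imputation distribution"
            )
        mu, sd = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - shift_sd * sd, width_sd * sd, size=int(miss.sum()))
        values[miss, j] = np.power(2.0, draws)
    return AnalyteMatrix(
        pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns),
        matrix.samples,
    )


def _vectorised_t(x: np.ndarray, y: np.ndarray, pooled: bool) -> np.ndarray:
    """Row-wise two-tailed t-test p-values, NaN-aware, with the zero-variance
    convention of :func:`two_tailed_t_test`."""
    res = stats.ttest_ind(
        x, y, axis=1, equal_var=pooled, nan_policy="omit"
    )
    p = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance: p is NaN; equal means -> 1, unequal -> 0
    mx, my = np.nanmean(x, axis=1), np.nanmean(y, axis=1)
    degenerate = np.isnan(p) & ~np.isnan(mx) & ~np.isnan(my)
    p[degenerate & (mx == my)] = 1.0
    p[degenerate & (mx != my)] = 0.0
    return p


def differential_table(
    matrix: AnalyteMatrix,
    alpha: float = 0.05,
    log_transform: bool = True,
    pooled: bool = True,
    fdr: bool = False,
) -> pd.DataFrame:
    """One directional call per (analyte, cell line, timepoint).

    Testing happens on log2 intensities when ``log_transform`` is set (the
    convention for label-free proteomics layers) and on the raw scale
    otherwise (kit-style metabolite panels); the reported effect size is the
    percent-of-control on the raw scale either way. Strata lacking a vehicle
    or drug group are skipped with a warning. With ``fdr=True`` directions are
    assigned on Benjamini-Hochberg adjusted p-values (reported as ``p_adj``).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    matrix = matrix.average_technical_replicates()
    frames = []
    for cell_line, timepoint in strata(matrix.samples):
        veh = matrix.group_columns(cell_line, timepoint, VEHICLE)
        drg = matrix.group_columns(cell_line, timepoint, DRUG)
        if not veh or not drg:
            warnings.warn(
                f"stratum ({cell_line}, {timepoint} h) lacks a "
                f"{'vehicle' if not veh else 'drug'} group; skipped"
            )
            continue
        raw_v = matrix.values[veh].to_numpy(dtype=float)
        raw_d = matrix.values[drg].to_numpy(dtype=float)
        if log_transform:
            with np.errstate(divide="ignore"):
                test_v, test_d = np.log2(raw_v), np.log2(raw_d)
        else:
            test_v, test_d = raw_v, raw_d
        p = _vectorised_t(test_d, test_v, pooled)

        control_mean = np.nanmean(raw_v, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_reps = raw_d / control_mean[:, None] * 100.0
        pct = np.nanmean(pct_reps, axis=1)
        n_obs = (~np.isnan(pct_reps)).sum(axis=1)
        sd = np.where(n_obs > 1, np.nanstd(pct_reps, axis=1, ddof=1), 0.0)

        frame = pd.DataFrame(
            {
                "analyte": matrix.values.index,
                "cell_line": cell_line,
                "timepoint_h": timepoint,
                "pct_of_control": pct,
                "sd_pct": sd,
                "p_value": p,
            }
        )
        if fdr:
            from statsmodels.stats.multitest import multipletests

            ok = ~np.isnan(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            frame["p_adj"] = adj
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "analyte", "cell_line", "timepoint_h",
                "pct_of_control", "sd_pct", "p_value", "direction",
            ]
        )
    calls = pd.concat(frames, ignore_index=True)
    crit = calls["p_adj"] if fdr else calls["p_value"]
    direction = np.full(len(calls), UNCHANGED, dtype=object)
    significant = crit < alpha
    direction[significant & (calls["pct_of_control"] > 100)] = UP
    direction[significant & (calls["pct_of_control"] < 100)] = DOWN
    calls["direction"] = direction
    return calls


def aggregate_class_summary(calls: pd.DataFrame, class_map) -> pd.DataFrame:
    """Mean +/- sample SD of percent-of-control per (class, cell line, time).

    ``class_map`` maps analyte id to a class label (e.g. metabolite class);
    analytes without a class are dropped with a warning. A single-member class
    gets SD 0 by convention.
    """
    known = calls["analyte"].isin(class_map.keys() if hasattr(class_map, "keys") else class_map)
    if (~known).any():
        warnings.warn(f"dropping {int((~known).sum())} calls without a class assignment")
    sub = calls.loc[known].copy()
    sub["class"] = sub["analyte"].map(class_map)
    rows = []
    for (cls, cell_line, t), grp in sub.groupby(["class", "cell_line", "timepoint_h"]):
        pcts = grp["pct_of_control"].to_numpy()
        sd = float(pcts.std(ddof=1)) if len(pcts) > 1 else 0.0
        rows.append((cls, cell_line, t, float(pcts.mean()), sd, len(pcts)))
    return pd.DataFrame(
        rows, columns=["class", "cell_line", "timepoint_h", "mean_pct", "sd_pct", "n"]
    )
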