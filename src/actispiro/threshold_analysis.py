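"""Activity-intensity thresholds from coefficient surfaces.

For each smoking group's fitted coefficient surface, the threshold is the
lowest acceleration above which the association with lung function is
positive and significant all the way to the top of the group's occupied
intensity range (an unbroken significant-positive run; isolated significant
pixels do not define a threshold).  Each participant's daily minutes above
the threshold then enter a within-group linear model of the reconstructed
FEV1 (volume at 1 s) or FVC (volume at 5 s), adjusted for the same scalar
covariates as the functional model, yielding the change in ml per
10 min/day above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .activity_density import inverse_transform, transform_acc
from .fof_regression import CoefficientSurface, FofFit, FOF_COVARIATES

#: the top of a group's usable intensity range excludes the highest-intensity
#: tail holding this fraction of the group's pooled activity mass
SUPPORT_TAIL_MASS = 0.01


@dataclass
class ThresholdResult:
    group: str
    outcome_time: float  # 1 s for FEV1, 5 s for FVC
    threshold_g: float | None
    delta_per_10min: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0


def trapz_tail(grid: np.ndarray, f: np.ndarray, x_star: float) -> float:
    """Trapezoid integral of f over [x_star, grid end], with linear
    interpolation inside the cell containing x_star."""
    if x_star <= grid[0]:
        return float(np.trapezoid(f, grid))
    if x_star >= grid[-1]:
        return 0.0
    j = int(np.searchsorted(grid, x_star))
    f_star = float(np.interp(x_star, grid, f))
    xs = np.concatenate([[x_star], grid[j:]])
    fs = np.concatenate([[f_star], f[j:]])
    return float(np.trapezoid(fs, xs))


def group_support_limit(
    F_group: np.ndarray, grid: np.ndarray, tail_mass: float = SUPPORT_TAIL_MASS
) -> float:
    """Upper limit of the group's occupied intensity range.

    Gaussian-kernel (and mixture) densities are positive everywhere, so
    "where the group has mass" is made operational through pooled mass: the
    limit is the largest grid x below which all but ``tail_mass`` of the
    group's pooled activity distribution lies.  Coefficient surfaces beyond
    it rest on the top percentile of person-time and are treated as
    unidentified.
    """
    fbar = F_group.mean(axis=0)
    total = np.trapezoid(fbar, grid)
    tail = np.array([trapz_tail(grid, fbar, x) for x in grid]) / total
    below = np.flatnonzero(tail >= tail_mass)
    if below.size == 0:
        return float(grid[0])
    return float(grid[below[-1]])


def find_threshold(
    surface: CoefficientSurface, t: float, x_upper: float | None = None
) -> float | None:
    """Smallest acceleration (g) with an unbroken significant-positive run.

    Scans the surface slice at time ``t`` and returns the back-transformed
    acceleration e^x - 1 of the smallest grid x* such that beta(x, t) > 0
    and the significance mask holds for every grid x in [x*, x_upper].
    Returns None when no such point exists (a valid outcome).
    """
    s = surface.slice_at(t)
    grid = s["x_grid"]
    iu = grid.size - 1 if x_upper is None else int(np.searchsorted(grid, x_upper))
    iu = min(iu, grid.size - 1)
    ok = (s["beta"] > 0) & s["mask"]
    run = np.logical_and.accumulate(ok[: iu + 1][::-1])[::-1]
    hits = np.flatnonzero(run)
    if hits.size == 0:
        return None
    return float(inverse_transform(grid[hits[0]]))


def time_above_threshold_density(
    f: np.ndarray, T: float, grid: np.ndarray, threshold_g: float
) -> float:
    """Daily minutes above threshold via the density path: T * tail mass."""
    x_star = float(transform_acc(np.array([threshold_g]))[0])
    if x_star > grid[-1]:
        return 0.0
    return float(T) * trapz_tail(grid, f, x_star)


def time_above_threshold_epochs(
    waking_epochs: pd.DataFrame,
    validities: pd.DataFrame,
    threshold_g: float,
    epoch_seconds: float | None = None,
) -> pd.DataFrame:
    """Daily minutes above threshold from epochs directly, 5:2 reweighted."""
    from .accelerometry import _weighted_daily_mean, infer_epoch_seconds

    if epoch_seconds is None:
        epoch_seconds = infer_epoch_seconds(waking_epochs)
    df = waking_epochs.copy()
    df["above"] = df["acc_g"] >= threshold_g
    per_day = (
        df.groupby(["participant_id", "day_index"])["above"].sum().reset_index()
    )
    per_day["above_min"] = per_day["above"] * epoch_seconds / 60.0
    valid = validities.loc[
        validities["valid"], ["participant_id", "day_index", "is_weekend"]
    ]
    per_day = per_day.merge(valid, on=["participant_id", "day_index"], how="inner")
    rows = [
        {
            "participant_id": pid,
            "above_threshold_min": _weighted_daily_mean(d, "above_min"),
        }
        for pid, d in per_day.groupby("participant_id")
    ]
    return pd.DataFrame(rows)


def estimate_delta(
    table: pd.DataFrame,
    outcome: str,
    covariates: list = FOF_COVARIATES,
    exposure: str = "above_threshold_min",
    min_n: int = 30,
) -> tuple[float, float, float, int] | None:
    """OLS slope of ``outcome`` on above-threshold minutes, per 10 min/day.

    Returns (delta, ci_low, ci_high, n), or None when the group is too
    small for a stable adjusted fit.
    """
    cols = [outcome, exposure] + [c for c in covariates if c in table.columns]
    df = table.dropna(subset=cols)
    if len(df) < min_n:
        return None
    X = df[[exposure] + [c for c in covariates if c in df.columns]].astype(float).copy()
    X[exposure] = X[exposure] / 10.0
    fit = sm.OLS(df[outcome].astype(float), sm.add_constant(X)).fit()
    ci = fit.conf_int().loc[exposure]
    return float(fit.params[exposure]), float(ci[0]), float(ci[1]), int(fit.nobs)


def threshold_table(
    fit: FofFit,
    density: dict,
    covariates: pd.DataFrame,
    outcome_times: tuple = (5.0, 1.0),
    group_col: str = "smoking_group",
) -> pd.DataFrame:
    """Table-3-shaped summary: per group and outcome time, the threshold and
    the adjusted change per 10 min/day above it.

    Outcomes are read off the reconstructed volume-time curves used in the
    functional fit (volume at 1 s for FEV1, at 5 s for FVC).
    """
    if fit.design.ids is None:
        raise ValueError("the fitted design must carry participant ids")
    di = {pid: i for i, pid in enumerate(density["participant_id"])}
    row_of = {pid: i for i, pid in enumerate(fit.design.ids)}
    cov = covariates.set_index("participant_id")
    t_grid = fit.design.t_grid
    rows = []
    for g in fit.group_labels:
        surf = fit.surface(g)
        g_ids = [pid for pid in fit.design.ids if cov.loc[pid, group_col] == g]
        if not g_ids:
            continue
        gi = np.array([di[pid] for pid in g_ids])
        x_up = group_support_limit(density["F"][gi], density["grid"])
        for t_out in outcome_times:
            thr = find_threshold(surf, t_out, x_upper=x_up)
            res = ThresholdResult(group=g, outcome_time=t_out, threshold_g=thr)
            if thr is not None:
                mins = np.array(
                    [
                        time_above_threshold_density(
                            density["F"][di[pid]],
                            density["T"][di[pid]],
                            density["grid"],
                            thr,
                        )
                        for pid in g_ids
                    ]
                )
                j_t = int(np.argmin(np.abs(t_grid - t_out)))
                # outcome read off each participant's reconstructed curve
                y_out = np.array([fit.design.Y[row_of[pid], j_t] for pid in g_ids])
                tab = cov.loc[
                    g_ids, [c for c in FOF_COVARIATES if c in cov.columns]
                ].copy()
                tab["above_threshold_min"] = mins
                tab["outcome"] = y_out
                est = estimate_delta(tab, "outcome")
                if est is not None:
                    res.delta_per_10min, res.ci_low, res.ci_high, res.n = est
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
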