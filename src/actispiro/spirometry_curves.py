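"""Spirometry curve reconstruction.

From each participant's trial table the blow with the largest FEV1 is
retained.  Its summary points — peak expiratory flow (PEF), forced
expiratory flows at 25/50/75% of expired FVC, and FVC — anchor a penalized
cubic-spline fit of the flow-volume curve F(v).  The expired-air
volume-time curve y(t) is then the solution of the autonomous ODE

    dy/dt = F(y),   y(1 s) = FEV1,

integrated forward to the end of the test and backward toward the peak.
Because F(0) = 0 makes y ≡ 0 a degenerate solution, the curve is anchored
at 1 s rather than at zero volume; the unresolvable early rising limb
(before the peak flow volume) is represented by a linear volume segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.integrate import solve_ivp

TRIAL_FIELDS = ["pef", "fef25", "fef50", "fef75", "fvc", "fev1"]

#: expired-volume fraction at which peak flow is assumed to occur
V_PEF_FRAC = 0.12
#: integration stops once y reaches (1 - NEAR_FVC_EPS) * fvc (stiff asymptote)
NEAR_FVC_EPS = 1e-3
T_MAX = 6.0
DT_OUT = 0.01


@dataclass
class SpirometrySummary:
    participant_id: object
    pef: float
    fef25: float
    fef50: float
    fef75: float
    fvc: float
    fev1: float

    def validate(self) -> None:
        if not (0 < self.fev1 <= self.fvc):
            raise ValueError(f"{self.participant_id}: need 0 < FEV1 <= FVC")
        flows = (self.pef, self.fef25, self.fef50, self.fef75)
        if any(f <= 0 for f in flows):
            raise ValueError(f"{self.participant_id}: flows must be positive")
        if self.pef < max(self.fef25, self.fef50, self.fef75):
            raise ValueError(
                f"{self.participant_id}: PEF must be the maximum flow"
            )


def select_best_blow(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain, per participant, the complete trial with the largest FEV1.

    Trials with any of the six summary fields missing are not eligible;
    participants with no eligible trial are excluded and reported.  Ties on
    FEV1 keep the first-listed trial.

    Returns ``(best, excluded)`` where ``best`` has one row per retained
    participant and ``excluded`` lists participant ids with a reason.
    """
    complete = trials.dropna(subset=TRIAL_FIELDS)
    best_rows = []
    for pid, d in complete.groupby("participant_id", sort=False):
        i = int(np.argmax(d["fev1"].to_numpy()))  # first max on ties
        best_rows.append(d.iloc[i])
    best = (
        pd.DataFrame(best_rows).reset_index(drop=True)
        if best_rows
        else pd.DataFrame(columns=trials.columns)
    )
    all_ids = pd.unique(trials["participant_id"])
    kept = set(best["participant_id"]) if len(best) else set()
    excluded = pd.DataFrame(
        {
            "participant_id": [pid for pid in all_ids if pid not in kept],
            "reason": "no complete spirometry trial",
        }
    )
    return best, excluded


# ---------------------------------------------------------------------------
# penalized-spline flow-volume fit
# ---------------------------------------------------------------------------


def _bspline_design(s: np.ndarray, n_basis: int, degree: int = 3):
    """Clamped uniform B-spline design matrix on [0, 1]."""
    inner = np.linspace(0.0, 1.0, n_basis - degree + 1)
    knots = np.concatenate(
        [np.full(degree, 0.0), inner, np.full(degree, 1.0)]
    )
    s = np.clip(s, 0.0, 1.0 - 1e-12)
    return BSpline.design_matrix(s, knots, degree).toarray(), knots


def _second_diff(k: int) -> np.ndarray:
    d = np.zeros((k - 2, k))
    for i in range(k - 2):
        d[i, i : i + 3] = (1.0, -2.0, 1.0)
    return d


@dataclass
class FlowVolumeCurve:
    """Fitted flow-volume curve with a linear rising limb below v_pef."""

    participant_id: object
    fvc: float
    pef: float
    v_pef: float
    coef: np.ndarray
    knots: np.ndarray
    degree: int
    lam: float
    anchor_max_err: float

    def flow(self, v):
        """Flow (ml/s) at expired volume v (ml); clipped at zero."""
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        rising = (v >= 0) & (v < self.v_pef)
        out[rising] = self.pef * v[rising] / self.v_pef
        mid = (v >= self.v_pef) & (v <= self.fvc)
        if mid.any():
            s = (v[mid] - self.v_pef) / (self.fvc - self.v_pef)
            spl = BSpline(self.knots, self.coef, self.degree, extrapolate=False)
            out[mid] = spl(np.clip(s, 0.0, 1.0))
        return np.maximum(out, 0.0)

    @property
    def v_grid(self):
        return np.linspace(0.0, self.fvc, 512)

    @property
    def F(self):
        return self.flow(self.v_grid)


def fit_flow_volume(
    summary: SpirometrySummary,
    lam: float | None = None,
    v_pef_frac: float = V_PEF_FRAC,
    n_basis: int = 8,
    lam_grid: np.ndarray | None = None,
) -> FlowVolumeCurve:
    """Penalized cubic-spline fit of F(v) through the summary anchors.

    Anchors: (v_pef, PEF), (0.25 fvc, FEF25), (0.50 fvc, FEF50),
    (0.75 fvc, FEF75) and (fvc, 0); the terminal anchor is enforced exactly
    as a linear constraint.  A second-difference penalty regularizes the
    under-determined basis; the smoothing parameter is chosen by GCV over a
    log-spaced grid, subject to a floor: candidates whose fit dips below
    zero on a dense volume grid or misses any anchor by more than 2% of PEF
    are rejected (smallest-violation fallback if none qualify).
    """
    summary.validate()
    fvc, pef = summary.fvc, summary.pef
    v_pef = v_pef_frac * fvc
    if not v_pef < 0.25 * fvc:
        raise ValueError("v_pef_frac must place the peak before 25% FVC")
    v_anchor = np.array([v_pef, 0.25 * fvc, 0.50 * fvc, 0.75 * fvc, fvc])
    y = np.array([pef, summary.fef25, summary.fef50, summary.fef75, 0.0])

    s_anchor = (v_anchor - v_pef) / (fvc - v_pef)
    B, knots = _bspline_design(s_anchor, n_basis)
    # exact terminal constraint F(fvc)=0
    a_end, _ = _bspline_design(np.array([1.0]), n_basis)
    a_end = a_end.ravel()
    D = _second_diff(n_basis)
    P = D.T @ D
    s_dense = np.linspace(0.0, 1.0, 200)
    B_dense, _ = _bspline_design(s_dense, n_basis)

    def solve(l):
        k = n_basis
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = B.T @ B + l * P
        kkt[:k, k] = a_end
        kkt[k, :k] = a_end
        rhs = np.concatenate([B.T @ y, [0.0]])
        theta = np.linalg.solve(kkt, rhs)[:k]
        return theta

    if lam is not None:
        grid = np.array([float(lam)])
    else:
        # dimensionless: response and coefficients both carry the pef scale
        grid = (
            np.geomspace(1e-8, 1.0, 17) if lam_grid is None else np.asarray(lam_grid)
        )
    candidates = []
    for l in grid:
        theta = solve(l)
        fit = B @ theta
        err = np.max(np.abs(fit - y)) / pef
        neg = -min(float((B_dense @ theta).min()), 0.0) / pef
        # GCV with ridge effective df (constraint ignored in the df count)
        H = B @ np.linalg.solve(B.T @ B + l * P, B.T)
        edf = np.trace(H)
        rss = float(((fit - y) ** 2).sum())
        denom = max(len(y) - edf, 0.25)
        gcv = len(y) * rss / denom**2
        candidates.append((l, theta, err, neg, gcv))

    feasible = [c for c in candidates if c[2] <= 0.02 and c[3] <= 1e-9]
    if feasible:
        l, theta, err, _, _ = min(feasible, key=lambda c: c[4])
    else:  # fall back to least total violation, fitted flows clipped at 0
        l, theta, err, _, _ = min(candidates, key=lambda c: c[2] + c[3])

    return FlowVolumeCurve(
        participant_id=summary.participant_id,
        fvc=fvc,
        pef=pef,
        v_pef=v_pef,
        coef=theta,
        knots=knots,
        degree=3,
        lam=float(l),
        anchor_max_err=float(err),
    )


# ---------------------------------------------------------------------------
# volume-time curve: dy/dt = F(y), y(1 s) = FEV1
# ---------------------------------------------------------------------------


@dataclass
class VolumeTimeCurve:
    participant_id: object
    t_grid: np.ndarray
    y: np.ndarray
    fvc: float
    fev1: float

    def at(self, t: float) -> float:
        return float(np.interp(t, self.t_grid, self.y))


def solve_volume_time(
    flow,
    fev1: float,
    fvc: float,
    v_pef: float,
    participant_id=None,
    t_max: float = T_MAX,
    dt_out: float = DT_OUT,
    rtol: float = 1e-8,
) -> VolumeTimeCurve:
    """Integrate dy/dt = F(y) from the anchor y(1 s) = FEV1.

    ``flow`` is a callable F(y).  Forward integration runs to ``t_max`` or
    until y reaches (1 - 1e-3) fvc, after which y is held constant (F -> 0
    makes the asymptote stiff).  Backward integration runs from the anchor
    toward the time where y = v_pef; the rising limb before the peak is not
    identifiable from summary data and is prepended as a linear volume
    segment from (0, 0).  Output is resampled to a fixed ``dt_out`` grid
    with y(1) = FEV1 exactly.
    """
    f_at_anchor = float(flow(np.array([fev1]))[0])
    if f_at_anchor <= 0:
        raise ValueError(
            f"{participant_id}: F(FEV1) <= 0; flow-volume fit inconsistent "
            "with the 1-s anchor"
        )
    y_stop = (1.0 - NEAR_FVC_EPS) * fvc

    def rhs(t, y):
        return [float(flow(np.array([min(y[0], fvc)]))[0])]

    def hit_stop(t, y):
        return y[0] - y_stop

    hit_stop.terminal = True
    hit_stop.direction = 1.0

    fwd = solve_ivp(
        rhs,
        (1.0, t_max),
        [fev1],
        rtol=rtol,
        atol=1e-6 * fvc,
        dense_output=True,
        events=hit_stop,
        max_step=0.1,
    )
    if not fwd.success:
        raise RuntimeError(f"{participant_id}: forward integration failed")
    t_stop = fwd.t_events[0][0] if len(fwd.t_events[0]) else t_max

    def hit_pef(t, y):
        return y[0] - v_pef

    hit_pef.terminal = True
    hit_pef.direction = -1.0

    bwd = solve_ivp(
        rhs,
        (1.0, 0.0),
        [fev1],
        rtol=rtol,
        atol=1e-6 * fvc,
        dense_output=True,
        events=hit_pef,
        max_step=0.1,
    )
    if not bwd.success:
        raise RuntimeError(f"{participant_id}: backward integration failed")
    t_pef = bwd.t_events[0][0] if len(bwd.t_events[0]) else 0.0
    t_pef = max(t_pef, 0.0)

    t_grid = np.round(np.arange(0.0, t_max + dt_out / 2, dt_out), 10)
    y = np.empty_like(t_grid)
    ramp = t_grid < t_pef
    if t_pef > 0:
        y[ramp] = v_pef * t_grid[ramp] / t_pef
    back = (~ramp) & (t_grid < 1.0)
    y[back] = bwd.sol(t_grid[back])[0]
    mid = (t_grid >= 1.0) & (t_grid <= t_stop)
    y[mid] = fwd.sol(np.minimum(t_grid[mid], fwd.t[-1]))[0]
    tail = t_grid > t_stop
    y[tail] = fwd.sol(np.full(tail.sum(), fwd.t[-1]))[0] if tail.any() else y[tail]

    i1 = int(np.argmin(np.abs(t_grid - 1.0)))
    y[i1] = fev1  # anchor exactly on the output grid
    y = np.minimum(np.maximum.accumulate(np.clip(y, 0.0, fvc)), fvc)
    return VolumeTimeCurve(
        participant_id=participant_id, t_grid=t_grid, y=y, fvc=fvc, fev1=fev1
    )


def reconstruct_participant(
    summary: SpirometrySummary,
    lam: float | None = None,
    v_pef_frac: float = V_PEF_FRAC,
    t_max: float = T_MAX,
) -> tuple[FlowVolumeCurve, VolumeTimeCurve]:
    """Summary -> penalized-spline F(v) -> volume-time curve y(t)."""
    curve = fit_flow_volume(summary, lam=lam, v_pef_frac=v_pef_frac)
    vt = solve_volume_time(
        curve.flow,
        summary.fev1,
        summary.fvc,
        curve.v_pef,
        participant_id=summary.participant_id,
        t_max=t_max,
    )
    return curve, vt


def reconstruct_cohort(
    best_trials: pd.DataFrame,
    v_pef_frac: float = V_PEF_FRAC,
    t_max: float = T_MAX,
) -> dict:
    """Volume-time matrix (participants x 0.01 s grid) for a trial table."""
    ids, rows, failures = [], [], []
    t_grid = None
    for _, r in best_trials.iterrows():
        summ = SpirometrySummary(
            participant_id=r["participant_id"],
            **{k: float(r[k]) for k in TRIAL_FIELDS},
        )
        try:
            _, vt = reconstruct_participant(summ, v_pef_frac=v_pef_frac, t_max=t_max)
        except (ValueError, RuntimeError) as exc:
            failures.append((r["participant_id"], str(exc)))
            continue
        ids.append(r["participant_id"])
        rows.append(vt.y)
        t_grid = vt.t_grid
    return {
        "participant_id": np.array(ids, dtype=object),
        "t_grid": t_grid,
        "Y": np.vstack(rows) if rows else np.empty((0, 0)),
        "failures": failures,
    }


def write_volume_matrix(vt: dict, path) -> None:
    """Volume-time matrix as CSV: one row per participant, t-grid header."""
    df = pd.DataFrame(vt["Y"], columns=[f"{t:.4g}" for t in vt["t_grid"]])
    df.insert(0, "participant_id", vt["participant_id"])
    df.to_csv(path, index=False)


def read_volume_matrix(path) -> dict:
    df = pd.read_csv(path)
    return {
        "participant_id": df["participant_id"].to_numpy(),
        "t_grid": np.array([float(c) for c in df.columns[1:]]),
        "Y": df.iloc[:, 1:].to_numpy(dtype=float),
        "failures": [],
    }
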