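"""Synthetic cohort generator with known planted structure.

Emulates the data layout of an accelerometer + spirometry study of older
adults: per participant, nine 24-hour days of 5-second epoch wrist
accelerations with a sleep log, five spirometry attempts summarized by
(PEF, FEF25, FEF50, FEF75, FVC, FEV1), and a covariate table with smoking
history.  Every signal the downstream pipeline is supposed to recover is
planted explicitly and serialized alongside the data:

* epoch accelerations follow a two-component lognormal mixture (sedentary-
  dominant + active component) whose parameters differ by smoking group and
  participant, reproducing the right skew that the log(1+a) transform
  presumes;
* spirometry outcomes are built as covariate effects plus a group-specific
  activity effect — so many ml of FVC per daily minute spent above a
  group-specific acceleration threshold — plus Gaussian noise, so the
  threshold and effect size are exactly recoverable;
* the full volume-time curve of each blow comes from a parametric
  flow-volume template whose exact summary points and time course are
  available in closed or quadrature form, giving the curve-reconstruction
  stages a ground truth.

`simulate_fof_design` additionally builds design matrices for which the
function-on-function regression model holds *literally* (response generated
from a planted coefficient surface), for estimator-level recovery and
type-I-error studies without the epoch-level machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

GROUPS = ("current", "recent_ex", "longterm_ex", "never")

SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class MixtureParams:
    """Two-component lognormal mixture for epoch accelerations (g units).

    ``w_active`` is the probability an awake epoch comes from the active
    component; remaining epochs come from the sedentary-dominant component.
    Means are on the natural-log-g scale.
    """

    w_active: float
    mu_sed: float = np.log(0.012)
    sigma_sed: float = 0.9
    mu_act: float = np.log(0.08)
    sigma_act: float = 0.8

    def validate(self, name: str) -> None:
        if not 0.0 <= self.w_active <= 1.0:
            raise ValueError(f"{name}: w_active must lie in [0, 1]")
        if self.sigma_sed <= 0 or self.sigma_act <= 0:
            raise ValueError(f"{name}: mixture sigmas must be positive")

    def prob_above(self, acc_g: float) -> float:
        """P(epoch acceleration >= acc_g) under the mixture."""
        la = np.log(acc_g)
        p_act = norm.sf((la - self.mu_act) / self.sigma_act)
        p_sed = norm.sf((la - self.mu_sed) / self.sigma_sed)
        return float(self.w_active * p_act + (1.0 - self.w_active) * p_sed)


#: group mixtures: current smokers are the least active (Table-1-like
#: sedentary/light/MVPA magnitudes: roughly 674/240/69 min per day)
DEFAULT_MIXTURES = {
    "current": MixtureParams(w_active=0.15),
    "recent_ex": MixtureParams(w_active=0.18),
    "longterm_ex": MixtureParams(w_active=0.185),
    "never": MixtureParams(w_active=0.18),
}


@dataclass
class PlantedEffect:
    """Group-specific activity effect on FVC: ``effect_ml_per_min`` ml of
    FVC per daily minute spent at accelerations >= ``threshold_g``."""

    threshold_g: float
    effect_ml_per_min: float


#: graded thresholds (lowest in current smokers) and effect sizes on the
#: scale of tens of ml per 10 min/day
DEFAULT_SURFACE = {
    "current": PlantedEffect(0.054, 3.5),
    "recent_ex": PlantedEffect(0.094, 3.6),
    "longterm_ex": PlantedEffect(0.074, 1.5),
    "never": PlantedEffect(0.161, 1.3),
}

#: covariate effects on FVC (ml per unit); "smoking" holds additive group
#: offsets ordered as GROUPS
DEFAULT_SCALAR_EFFECTS = {
    "age": -25.0,  # per year
    "sex": -576.0,  # women vs men
    "ethnicity": -120.0,  # non-Caucasian vs Caucasian
    "height_cm": 32.0,  # per cm
    "weight_kg": -8.0,  # per kg
    "respiratory_disease": -350.0,
    "n_chronic": -40.0,
    "smoking": (-230.0, -180.0, -30.0, 0.0),
}


@dataclass
class CohortConfig:
    n_participants: int
    n_days: int = 9
    epoch_seconds: float = 5.0
    group_proportions: tuple = (0.028, 0.048, 0.408, 0.516)
    mixtures: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURES))
    planted_surface: dict = field(default_factory=lambda: dict(DEFAULT_SURFACE))
    planted_scalar_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_SCALAR_EFFECTS)
    )
    fev1_ratio_offsets: tuple = (-0.05, -0.04, -0.01, 0.0)
    noise_sd: float = 300.0
    p_gap_day: float = 0.15
    p_invalid_day: float = 0.03
    p_incomplete_spiro: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_days < 3:
            raise ValueError("n_days must be at least 3 (first/last are dropped)")
        if self.epoch_seconds <= 0 or 60.0 % self.epoch_seconds != 0:
            raise ValueError("epoch_seconds must be positive and divide 60")
        props = np.asarray(self.group_proportions, dtype=float)
        if props.size != 4 or np.any(props < 0):
            raise ValueError("group_proportions must be 4 non-negative numbers")
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("group_proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for g in GROUPS:
            self.mixtures[g].validate(g)
        for p in (self.p_gap_day, self.p_invalid_day, self.p_incomplete_spiro):
            if not 0.0 <= p <= 1.0:
                raise ValueError("day/spirometry failure probabilities must be in [0,1]")


# ---------------------------------------------------------------------------
# parametric flow-volume templates
# ---------------------------------------------------------------------------


class FlowVolumeTemplate:
    """Parametric flow-volume curve with exact summaries and time course.

    ``kind='power'``: F(v) = pef * g(v)/g(v_peak) with
    g(v) = v^a (fvc-v)^b0 exp(-c v / fvc) and a chosen so the single
    maximum pef sits at v_peak = v_peak_frac * fvc; F(fvc) = 0.  The decay
    knob c >= 0 lowers mid-curve flows (hence FEV1) while the sublinear
    terminal exponent b0 < 1 keeps the blow finishing in finite time, so
    curves plateau near FVC within a realistic 6-second test.

    ``kind='linear'``: F(v) = (pef/fvc) * (fvc - v), peaking at v = 0, with
    the closed-form volume-time curve y(t) = fvc * (1 - exp(-pef t / fvc)).
    """

    def __init__(
        self,
        fvc: float,
        pef: float,
        kind: str = "power",
        c: float = 2.4,
        terminal_exponent: float = 0.85,
        v_peak_frac: float = 0.12,
    ):
        if fvc <= 0 or pef <= 0:
            raise ValueError("fvc and pef must be positive")
        self.fvc, self.pef, self.kind = float(fvc), float(pef), kind
        if kind == "power":
            if c < 0 or terminal_exponent <= 0 or not 0 < v_peak_frac < 0.25:
                raise ValueError(
                    "power template needs c >= 0, terminal_exponent > 0 and "
                    "0 < v_peak_frac < 0.25"
                )
            self.v_peak = v_peak_frac * fvc
            self.c = float(c)
            self.b0 = float(terminal_exponent)
            self.a = self.b0 * self.v_peak / (fvc - self.v_peak) + c * v_peak_frac
            if self.a >= 1.0:
                raise ValueError("shape too steep: a >= 1 makes onset time diverge")
        elif kind == "linear":
            self.v_peak = 0.0
            self.k = pef / fvc
        else:
            raise ValueError(f"unknown template kind {kind!r}")
        self._t_of_v = None

    def flow(self, v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        inside = (v >= 0) & (v <= self.fvc)
        if self.kind == "linear":
            out[inside] = self.k * (self.fvc - v[inside])
        else:
            vv = v[inside]
            with np.errstate(divide="ignore", invalid="ignore"):
                log_g = (
                    self.a * np.log(vv)
                    + self.b0 * np.log(self.fvc - vv)
                    - self.c * vv / self.fvc
                )
            log_gp = (
                self.a * np.log(self.v_peak)
                + self.b0 * np.log(self.fvc - self.v_peak)
                - self.c * self.v_peak / self.fvc
            )
            val = self.pef * np.exp(log_g - log_gp)
            val[~np.isfinite(val)] = 0.0
            out[inside] = val
        return out

    # -- exact time course ---------------------------------------------------

    def _time_table(self, n: int = 4000):
        """t(v) from blow start by quadrature of dt = dv / F(v)."""
        if self._t_of_v is not None:
            return self._t_of_v
        if self.kind == "linear":
            v = np.linspace(0.0, self.fvc * (1.0 - 1e-9), n)
            t = -np.log(1.0 - v / self.fvc) / self.k
        else:
            v0 = 1e-5 * self.fvc
            v = np.concatenate(
                [
                    np.geomspace(v0, self.v_peak, n // 4),
                    np.linspace(self.v_peak, self.fvc * (1 - 1e-7), n)[1:],
                ]
            )
            inv_f = 1.0 / self.flow(v)
            t = np.concatenate([[0.0], np.cumsum(np.diff(v) * 0.5 * (inv_f[1:] + inv_f[:-1]))])
            # analytic head: near 0, F ~ pef (v/vp)^a ((fvc)/(fvc-vp))^b scaling
            head = v0 / ((1.0 - self.a) * self.flow(np.array([v0]))[0])
            t = t + head
        self._t_of_v = (t, v)
        return self._t_of_v

    def volume_time(self, t_grid) -> np.ndarray:
        """Exact y(t) (t from blow start); constant at fvc past the data."""
        t_grid = np.asarray(t_grid, dtype=float)
        if self.kind == "linear":
            return self.fvc * (1.0 - np.exp(-self.k * t_grid))
        t, v = self._time_table()
        return np.interp(t_grid, t, v, left=0.0, right=v[-1])

    @property
    def fev1(self) -> float:
        return float(self.volume_time(np.array([1.0]))[0])

    def summary(self, participant_id=None) -> dict:
        """Exact summary points of the template."""
        f25, f50, f75 = self.flow(np.array([0.25, 0.50, 0.75]) * self.fvc)
        return {
            "participant_id": participant_id,
            "pef": self.pef,
            "fef25": float(f25),
            "fef50": float(f50),
            "fef75": float(f75),
            "fvc": self.fvc,
            "fev1": self.fev1,
        }


def generate_flow_volume_template(
    fvc: float, pef: float, kind: str = "power", **shape_params
) -> FlowVolumeTemplate:
    """Factory for parametric flow-volume templates (see class docstring)."""
    return FlowVolumeTemplate(fvc, pef, kind=kind, **shape_params)


def _template_for_fev1(
    fvc: float, pef: float, fev1_target: float, v_peak_frac: float = 0.12
) -> FlowVolumeTemplate:
    """Power template matching a target FEV1 by tuning the decay knob c."""

    def make(c):
        return FlowVolumeTemplate(fvc, pef, c=c, v_peak_frac=v_peak_frac)

    # keep a < 1 (finite blow-onset time)
    c_max = (0.999 - 0.85 * v_peak_frac / (1.0 - v_peak_frac)) / v_peak_frac

    def gap(c):
        return make(c).fev1 - fev1_target

    lo, hi = 0.01, c_max - 0.01
    if gap(lo) <= 0:  # even the gentlest decay cannot reach the target: clamp
        return make(lo)
    if gap(hi) >= 0:
        return make(hi)
    c = brentq(gap, lo, hi, xtol=1e-4)
    return make(c)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    epoch_table: pd.DataFrame
    sleep_log: pd.DataFrame
    spirometry_trials: pd.DataFrame
    covariates: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.epoch_table.to_csv(out / "epochs.csv", index=False)
        self.sleep_log.to_csv(out / "sleep_log.csv", index=False)
        self.spirometry_trials.to_csv(out / "spirometry_trials.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (MixtureParams, PlantedEffect)):
        return asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _draw_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    group_idx = rng.choice(4, size=n, p=np.asarray(cfg.group_proportions))
    sex = (rng.random(n) < 0.261).astype(int)  # 1 = women
    age = np.clip(rng.normal(69.2, 5.6, n), 60.0, 83.0)
    ethnicity = (rng.random(n) < 0.066).astype(int)  # 1 = non-Caucasian
    height = np.where(sex == 0, 175.0, 162.0) + rng.normal(0.0, 6.0, n)
    weight = 77.7 + 0.55 * (height - 170.8) + rng.normal(0.0, 11.0, n)
    resp_p = np.array([0.07, 0.15, 0.079, 0.075])[group_idx]
    respiratory = (rng.random(n) < resp_p).astype(int)
    n_chronic = rng.poisson(0.65, n)
    occupation = rng.choice(3, size=n, p=(0.455, 0.435, 0.11))
    education = rng.choice(5, size=n, p=(0.1, 0.2, 0.25, 0.25, 0.2))
    married = (rng.random(n) < 0.757).astype(int)
    alcohol = rng.choice(3, size=n, p=(0.30, 0.556, 0.144))
    fruitveg = (rng.random(n) < 0.803).astype(int)
    cigs = np.zeros(n)
    cur = group_idx == 0
    rec = group_idx == 1
    cigs[cur] = np.clip(rng.normal(12.9, 7.7, cur.sum()), 1.0, 60.0)
    cigs[rec] = np.clip(rng.normal(5.6, 8.0, rec.sum()), 0.0, 60.0)
    return pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "smoking": group_idx,  # 0 current .. 3 never
            "smoking_group": np.asarray(GROUPS, dtype=object)[group_idx],
            "sex": sex,
            "age": age,
            "ethnicity": ethnicity,
            "height_cm": height,
            "weight_kg": weight,
            "respiratory_disease": respiratory,
            "n_chronic": n_chronic,
            "occupational_position": occupation,
            "education": education,
            "married": married,
            "alcohol": alcohol,
            "fruitveg_daily": fruitveg,
            "cigs_per_day": cigs,
            "start_weekday": rng.integers(0, 7, n),  # weekday of day_index 1
        }
    )


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = _draw_covariates(config, rng)
    n = config.n_participants
    eps = config.epoch_seconds
    epochs_per_day = int(round(SECONDS_PER_DAY / eps))
    day_starts = np.arange(epochs_per_day) * eps

    epoch_frames = []
    sleep_rows = []
    minutes_above = np.zeros(n)
    realized_T = np.zeros(n)

    for i in range(n):
        g = GROUPS[cov.loc[i, "smoking"]]
        mix = config.mixtures[g]
        w_i, mu_sed_i, sig_sed_i, mu_act_i, sig_act_i = _participant_mixture(mix, rng)
        thr = config.planted_surface[g].threshold_g

        acc_all, worn_all, day_all, t_all = [], [], [], []
        n_above = 0
        n_waking_core = 0
        for d in range(1, config.n_days + 1):
            wake = float(np.clip(rng.normal(7 * 3600, 1200), 5 * 3600, 9 * 3600))
            onset = float(np.clip(rng.normal(23 * 3600, 1200), 21 * 3600, 25 * 3600 - eps))
            onset = min(onset, SECONDS_PER_DAY - eps)
            wake = day_starts[np.searchsorted(day_starts, wake)]
            onset = day_starts[np.searchsorted(day_starts, onset)]
            sleep_rows.append(
                {
                    "participant_id": i,
                    "day_index": d,
                    "weekday": int((cov.loc[i, "start_weekday"] + d - 1) % 7),
                    "wake_onset_s": wake,
                    "sleep_onset_s": onset,
                }
            )
            awake = (day_starts >= wake) & (day_starts < onset)
            n_awake = int(awake.sum())
            acc = np.empty(epochs_per_day)
            n_sleep = epochs_per_day - n_awake
            acc[~awake] = rng.lognormal(np.log(0.003), 0.5, n_sleep)
            active = rng.random(n_awake) < w_i
            day_acc = np.where(
                active,
                rng.lognormal(mu_act_i, sig_act_i, n_awake),
                rng.lognormal(mu_sed_i, sig_sed_i, n_awake),
            )
            # 5-s mean accelerations are bounded by the device's dynamic
            # range; cap the lognormal tail at a realistic 2 g
            day_acc = np.minimum(day_acc, 2.0)
            acc[awake] = day_acc

            worn = np.ones(epochs_per_day, dtype=bool)
            u = rng.random()
            if u < config.p_invalid_day:
                gap_len = rng.uniform(0.35, 0.60) * n_awake
            elif u < config.p_invalid_day + config.p_gap_day:
                gap_len = rng.uniform(30.0, 120.0) * 60.0 / eps
            else:
                gap_len = 0.0
            if gap_len >= 1.0:
                awake_idx = np.flatnonzero(awake)
                gap_len = int(min(gap_len, n_awake))
                start = rng.integers(0, n_awake - gap_len + 1)
                worn[awake_idx[start : start + gap_len]] = False

            if 2 <= d <= config.n_days - 1:
                n_above += int((day_acc >= thr).sum())
                n_waking_core += n_awake

            acc_all.append(acc.astype(np.float32))
            worn_all.append(worn)
            day_all.append(np.full(epochs_per_day, d, dtype=np.int16))
            t_all.append(day_starts.astype(np.float64))

        n_core_days = config.n_days - 2
        minutes_above[i] = n_above * eps / 60.0 / n_core_days
        realized_T[i] = n_waking_core * eps / 60.0 / n_core_days
        epoch_frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.full(
                        epochs_per_day * config.n_days, i, dtype=np.int32
                    ),
                    "day_index": np.concatenate(day_all),
                    "epoch_start_s": np.concatenate(t_all),
                    "acc_g": np.concatenate(acc_all),
                    "worn": np.concatenate(worn_all),
                }
            )
        )

    epoch_table = pd.concat(epoch_frames, ignore_index=True)
    sleep_log = pd.DataFrame(sleep_rows)

    # ---- spirometry outcomes from planted structure -------------------------
    eff = config.planted_scalar_effects
    smoking_offsets = np.asarray(eff.get("smoking", (0.0, 0.0, 0.0, 0.0)))
    gidx = cov["smoking"].to_numpy()
    fvc_true = (
        3650.0
        + eff.get("age", 0.0) * (cov["age"].to_numpy() - 69.2)
        + eff.get("sex", 0.0) * cov["sex"].to_numpy()
        + eff.get("ethnicity", 0.0) * cov["ethnicity"].to_numpy()
        + eff.get("height_cm", 0.0) * (cov["height_cm"].to_numpy() - 170.8)
        + eff.get("weight_kg", 0.0) * (cov["weight_kg"].to_numpy() - 77.7)
        + eff.get("respiratory_disease", 0.0) * cov["respiratory_disease"].to_numpy()
        + eff.get("n_chronic", 0.0) * cov["n_chronic"].to_numpy()
        + smoking_offsets[gidx]
    )
    effect_per_min = np.array(
        [config.planted_surface[GROUPS[k]].effect_ml_per_min for k in gidx]
    )
    fvc_true = fvc_true + effect_per_min * minutes_above
    fvc_true = fvc_true + rng.normal(0.0, config.noise_sd, n)
    fvc_true = np.maximum(fvc_true, 800.0)

    # FEV1/FVC kept above 0.72 so every synthetic blow plateaus by 6 s;
    # obstructive-range ratios are deliberately out of the generator's scope
    ratio = np.clip(
        0.78
        - 0.003 * (cov["age"].to_numpy() - 69.2)
        + np.asarray(config.fev1_ratio_offsets)[gidx]
        + rng.normal(0.0, 0.03, n),
        0.72,
        0.90,
    )
    fev1_true = ratio * fvc_true
    pef_true = np.clip(
        1.9 * (1.0 + rng.normal(0.0, 0.05, n)), 1.7, 2.2
    ) * fvc_true

    trial_rows = []
    incomplete = rng.random(n) < config.p_incomplete_spiro
    for i in range(n):
        tpl = _template_for_fev1(fvc_true[i], pef_true[i], fev1_true[i])
        s = tpl.summary(participant_id=i)
        for j in range(5):
            scale = 1.0 + rng.normal(0.0, 0.02)
            row = {"participant_id": i, "trial": j + 1}
            for k in ("pef", "fef25", "fef50", "fef75"):
                row[k] = s[k] * scale * (1.0 + rng.normal(0.0, 0.01))
            row["pef"] = max(row["pef"], row["fef25"], row["fef50"], row["fef75"])
            row["fvc"] = s["fvc"] * (1.0 + rng.normal(0.0, 0.012))
            row["fev1"] = min(s["fev1"] * (1.0 + rng.normal(0.0, 0.012)), row["fvc"])
            if incomplete[i]:
                row["fef50"] = np.nan
            trial_rows.append(row)
    trials = pd.DataFrame(trial_rows)

    truth = {
        "planted_surface": {g: asdict(config.planted_surface[g]) for g in GROUPS},
        "planted_scalar_effects": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in eff.items()
        },
        "noise_sd": config.noise_sd,
        "fvc_true": fvc_true.tolist(),
        "fev1_true": fev1_true.tolist(),
        "minutes_above_group_threshold": minutes_above.tolist(),
        "realized_waking_min": realized_T.tolist(),
        "seed": config.seed,
    }
    return SyntheticCohort(
        epoch_table=epoch_table,
        sleep_log=sleep_log,
        spirometry_trials=trials,
        covariates=cov,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# direct functional-design simulation (model holds literally)
# ---------------------------------------------------------------------------


def _participant_mixture(mix: MixtureParams, rng: np.random.Generator):
    """Participant-level mixture parameters around the group values.

    Between-person heterogeneity in the activity share, component locations
    and spreads is what makes the cohort's activity densities span several
    directions of variation — without it the functional design would be
    nearly rank-3 and coefficient surfaces unidentifiable off that span.
    """
    w = float(np.clip(mix.w_active + rng.normal(0.0, 0.05), 0.02, 0.6))
    mu_act = mix.mu_act + rng.normal(0.0, 0.30)
    mu_sed = mix.mu_sed + rng.normal(0.0, 0.20)
    sig_act = max(mix.sigma_act + rng.normal(0.0, 0.10), 0.3)
    sig_sed = max(mix.sigma_sed + rng.normal(0.0, 0.10), 0.3)
    return w, mu_sed, sig_sed, mu_act, sig_act


def mixture_density_x(
    grid: np.ndarray, w: float, mu_sed: float, sigma_sed: float, mu_act: float, sigma_act: float
) -> np.ndarray:
    """Exact density of x = log(1+a) when a is the lognormal mixture."""
    f = np.zeros_like(grid)
    pos = grid > 0
    a = np.expm1(grid[pos])
    la = np.log(a)
    jac = np.exp(grid[pos]) / a
    f[pos] = (
        w * norm.pdf((la - mu_act) / sigma_act) / sigma_act
        + (1.0 - w) * norm.pdf((la - mu_sed) / sigma_sed) / sigma_sed
    ) * jac
    norm_const = np.trapezoid(f, grid)
    return f / norm_const if norm_const > 0 else f


def reference_volume_profile(t_grid: np.ndarray) -> np.ndarray:
    """Normalized mean volume-time shape r(t) in [0, 1] (template-based)."""
    tpl = FlowVolumeTemplate(3600.0, 6900.0, c=2.4)
    y = tpl.volume_time(t_grid)
    return y / tpl.fvc


def simulate_fof_design(
    n: int,
    x_grid: np.ndarray,
    t_grid: np.ndarray,
    beta_x_by_group: dict,
    seed: int,
    group_probs: dict | None = None,
    gamma: dict | None = None,
    noise_sd: float = 300.0,
    mixtures: dict | None = None,
    t_profile: np.ndarray | None = None,
    beta_surface_by_group: dict | None = None,
    gamma_profile: np.ndarray | None = None,
):
    """Simulate (A, Y, Z, group) with the function-on-function model true.

    ``beta_x_by_group`` maps group label -> callable b_g(x) (ml of volume at
    the final time per unit of A-mass); the planted surface is separable,
    beta_g(x, t) = b_g(x) * r(t), with r the normalized volume profile.
    Alternatively ``beta_surface_by_group`` maps group label -> callable
    (x_grid, t_grid) -> full (Gx, Gt) surface, overriding the separable
    form (labels must match ``beta_x_by_group``'s keys).  Covariate
    functions are gamma_j(t) = c_j * r(t); noise is independent Gaussian
    with sd noise_sd * max(r(t), 0.05).

    Returns ``(design_dict, truth_dict)``; the design dict has keys
    A, Y, Z (DataFrame), group, x_grid, t_grid.
    """
    rng = np.random.default_rng(seed)
    labels = list(beta_x_by_group)
    if group_probs is None:
        p = np.full(len(labels), 1.0 / len(labels))
    else:
        p = np.array([group_probs[g] for g in labels], dtype=float)
        p = p / p.sum()
    group = rng.choice(len(labels), size=n, p=p)
    group_labels = np.asarray(labels, dtype=object)[group]

    if mixtures is None:
        mixtures = DEFAULT_MIXTURES
    base = [mixtures.get(g, MixtureParams(w_active=0.18)) for g in group_labels]

    F = np.empty((n, x_grid.size))
    for i in range(n):
        w_i, mu_sed_i, sig_sed_i, mu_act_i, sig_act_i = _participant_mixture(
            base[i], rng
        )
        F[i] = mixture_density_x(x_grid, w_i, mu_sed_i, sig_sed_i, mu_act_i, sig_act_i)
    T = np.clip(rng.normal(960.0, 45.0, n), 720.0, 1100.0)
    A = F * T[:, None]

    r = reference_volume_profile(t_grid) if t_profile is None else t_profile
    alpha = 3600.0 * r

    age = np.clip(rng.normal(69.2, 5.6, n), 60, 83) - 69.2
    sex = (rng.random(n) < 0.26).astype(float)
    height = rng.normal(0.0, 9.1, n)
    Z = pd.DataFrame({"age": age, "sex": sex, "height_cm": height})
    if gamma is None:
        gamma = {"age": -25.0, "sex": -576.0, "height_cm": 32.0}
    g_prof = r if gamma_profile is None else np.asarray(gamma_profile, dtype=float)
    gmat = np.zeros((n, t_grid.size))
    for name, c in gamma.items():
        gmat += np.outer(Z[name].to_numpy(), c * g_prof)

    w_trapz = _trapz_weights(x_grid)
    beta_true = {}
    functional = np.zeros((n, t_grid.size))
    for k, lab in enumerate(labels):
        if beta_surface_by_group is not None:
            surf = beta_surface_by_group[lab](x_grid, t_grid)  # (Gx, Gt)
        else:
            surf = np.outer(beta_x_by_group[lab](x_grid), r)
        beta_true[lab] = surf
        rows = group == k
        functional[rows] = (A[rows] * w_trapz) @ surf

    sig = noise_sd * np.maximum(r, 0.05)
    Y = alpha[None, :] + functional + gmat + rng.normal(0.0, 1.0, (n, t_grid.size)) * sig

    design = {
        "A": A,
        "Y": Y,
        "Z": Z,
        "group": group_labels,
        "x_grid": x_grid,
        "t_grid": t_grid,
    }
    truth = {
        "beta": beta_true,
        "gamma": gamma,
        "alpha": alpha,
        "t_profile": r,
        "noise_sd": noise_sd,
        "F": F,
        "T": T,
    }
    return design, truth


def simulate_scalar_table(
    n: int,
    slopes_per_10min: dict,
    seed: int,
    noise_sd: float = 300.0,
    outcome: str = "fvc",
    group_probs: tuple = (0.25, 0.25, 0.25, 0.25),
) -> pd.DataFrame:
    """Analysis-ready table with planted per-stratum MVPA slopes.

    ``slopes_per_10min`` maps group label -> ml change per 10 min/day of
    MVPA.  Covariate effects use the default planted values; exposure is
    drawn with realistic spread (MVPA mean ~69, sd ~36 min/day).
    """
    rng = np.random.default_rng(seed)
    cfg = CohortConfig(n_participants=n, seed=seed)
    cov = _draw_covariates(cfg, rng)
    cov["smoking"] = rng.choice(4, size=n, p=np.asarray(group_probs))
    cov["smoking_group"] = np.asarray(GROUPS, dtype=object)[cov["smoking"]]
    mvpa = np.clip(rng.normal(69.3, 36.7, n), 0.0, 300.0)
    light = np.clip(rng.normal(240.5, 58.1, n), 0.0, 600.0)
    sed = np.clip(rng.normal(673.9, 88.1, n), 120.0, 1100.0)
    waking = sed + light + mvpa
    eff = DEFAULT_SCALAR_EFFECTS
    slope_min = np.array([slopes_per_10min[g] / 10.0 for g in cov["smoking_group"]])
    y = (
        3650.0
        + eff["age"] * (cov["age"] - 69.2)
        + eff["sex"] * cov["sex"]
        + eff["ethnicity"] * cov["ethnicity"]
        + eff["height_cm"] * (cov["height_cm"] - 170.8)
        + eff["weight_kg"] * (cov["weight_kg"] - 77.7)
        + np.asarray(eff["smoking"])[cov["smoking"]]
        + slope_min * mvpa
        + rng.normal(0.0, noise_sd, n)
    )
    out = cov.copy()
    out["mvpa_min"] = mvpa
    out["light_min"] = light
    out["sedentary_min"] = sed
    out["waking_min"] = waking
    out[outcome] = y
    return out


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w
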