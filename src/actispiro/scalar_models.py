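"""Conventional scalar regression analysis of lung function on activity.

Linear models of FEV1 or FVC (ml) on daily minutes in one activity level,
reported per 10 min/day, with two adjustment sets:

* model 1 — age, sex, ethnicity, height, weight, smoking history and waking
  duration (so that more time in the exposure level trades off against the
  other levels within a fixed waking day);
* model 2 — model 1 plus occupational position, education, marital status,
  alcohol consumption, daily fruit/vegetable consumption, respiratory
  disease, number of chronic diseases, and cigarettes/day within current
  and recent ex-smokers.

Effect modification by smoking history is assessed two ways: stratum
slopes come from a single model with exposure x smoking-group interaction
terms (never smokers as reference), while the reported interaction p-value
is the 1-df Wald test on an exposure x ordinal-smoking product term
(smoking coded 0 = current .. 3 = never).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic_cohort import GROUPS

EXPOSURE_COLUMNS = {
    "sedentary": "sedentary_min",
    "light": "light_min",
    "mvpa": "mvpa_min",
    "above_threshold": "above_threshold_min",
}

MODEL1_NUMERIC = ["age", "height_cm", "weight_kg", "waking_min"]
MODEL1_BINARY = ["sex", "ethnicity"]
MODEL2_EXTRA_NUMERIC = ["n_chronic", "cigs_per_day"]
MODEL2_EXTRA_BINARY = ["married", "fruitveg_daily", "respiratory_disease"]
MODEL2_EXTRA_CATEGORICAL = ["occupational_position", "education", "alcohol"]


@dataclass
class ModelSpec:
    outcome: str = "fvc"
    exposure: str = "mvpa"
    adjustment: str = "model1"
    interaction_with_smoking: bool = False
    exclude_respiratory: bool = False

    def __post_init__(self):
        if self.exposure not in EXPOSURE_COLUMNS:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.adjustment not in ("model1", "model2"):
            raise ValueError("adjustment must be 'model1' or 'model2'")


@dataclass
class EffectEstimate:
    group: str  # "overall" or a smoking stratum
    beta_per_10min: float
    ci_low: float
    ci_high: float
    p_value: float
    p_interaction: float | None = None
    n: int = 0


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series.astype(int), prefix=prefix, drop_first=True)
    return d.astype(float)


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix (without constant) and outcome for the requested model.

    The exposure enters as ``exposure_10`` (minutes/10) so its coefficient
    reads directly in ml per 10 min/day.  Complete cases only; smoking
    history enters as group dummies with never smokers as reference.
    """
    cols_needed = (
        [spec.outcome, EXPOSURE_COLUMNS[spec.exposure], "smoking"]
        + MODEL1_NUMERIC
        + MODEL1_BINARY
    )
    if spec.adjustment == "model2":
        cols_needed += (
            MODEL2_EXTRA_NUMERIC + MODEL2_EXTRA_BINARY + MODEL2_EXTRA_CATEGORICAL
        )
    df = table.dropna(subset=[c for c in cols_needed if c in table.columns])
    if spec.exclude_respiratory:
        df = df[df["respiratory_disease"] == 0]

    X = pd.DataFrame(index=df.index)
    X["exposure_10"] = df[EXPOSURE_COLUMNS[spec.exposure]] / 10.0
    for c in MODEL1_NUMERIC + MODEL1_BINARY:
        X[c] = df[c].astype(float)
    for k, g in enumerate(GROUPS[:3]):  # never (code 3) is the reference
        X[f"smoking_{g}"] = (df["smoking"] == k).astype(float)
    if spec.adjustment == "model2":
        for c in MODEL2_EXTRA_NUMERIC + MODEL2_EXTRA_BINARY:
            X[c] = df[c].astype(float)
        for c in MODEL2_EXTRA_CATEGORICAL:
            X = pd.concat([X, _dummies(df[c], c)], axis=1)
    if spec.interaction_with_smoking:
        for k, g in enumerate(GROUPS[:3]):
            X[f"exposure_10:smoking_{g}"] = X["exposure_10"] * X[f"smoking_{g}"]

    # degenerate (constant) columns carry no information and break the fit;
    # empty smoking strata and single-valued covariates are dropped, along
    # with interactions built on a dropped stratum dummy
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if "exposure_10" in constant:
        raise ValueError("exposure has no variation in the analysis sample")
    for c in list(X.columns):
        if ":" in c and c.split(":", 1)[1] in constant:
            constant.append(c)
    X = X.drop(columns=sorted(set(constant)))
    return X, df[spec.outcome].astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    r = np.linalg.matrix_rank(arr)
    if r < arr.shape[1]:
        # identify offending columns via QR with pivoting
        from scipy.linalg import qr

        _, rmat, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(rmat))
        rank = int((diag >= diag.max() * 1e-10).sum())
        bad = np.asarray(piv)[rank:]
        names = ["const"] + list(X.columns)
        raise ValueError(
            "rank-deficient design; collinear columns: "
            + ", ".join(names[i] for i in bad)
        )


def _ols(X: pd.DataFrame, y: pd.Series):
    _check_rank(X)
    return sm.OLS(y, sm.add_constant(X.astype(float))).fit()


def interaction_p_ordinal(table: pd.DataFrame, spec: ModelSpec) -> float:
    """1-df Wald p for an exposure x ordinal-smoking product term."""
    base = ModelSpec(spec.outcome, spec.exposure, spec.adjustment, False,
                     spec.exclude_respiratory)
    X, y = build_design(table, base)
    smoking_ord = table.loc[X.index, "smoking"].astype(float)
    if smoking_ord.nunique() <= 1:
        return float("nan")  # effect modification undefined with one stratum
    X = X.copy()
    X["exposure_10:smoking_ord"] = X["exposure_10"] * smoking_ord
    fit = _ols(X, y)
    return float(fit.pvalues["exposure_10:smoking_ord"])


def fit_activity_model(table: pd.DataFrame, spec: ModelSpec) -> list[EffectEstimate]:
    """OLS estimate(s) of the activity-lung function association.

    Without interaction: one overall estimate (ml per 10 min/day).  With
    interaction: one estimate per smoking stratum via linear combinations
    of the interaction model's coefficients, sharing its covariance, plus
    the ordinal 1-df interaction p-value attached to every stratum row.
    """
    X, y = build_design(table, spec)
    fit = _ols(X, y)
    n = int(fit.nobs)

    if not spec.interaction_with_smoking:
        ci = fit.conf_int().loc["exposure_10"]
        return [
            EffectEstimate(
                group="overall",
                beta_per_10min=float(fit.params["exposure_10"]),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p_value=float(fit.pvalues["exposure_10"]),
                n=n,
            )
        ]

    p_int = interaction_p_ordinal(table, spec)
    names = list(fit.params.index)
    out = []
    present = set(table.loc[X.index, "smoking"].unique()) if "smoking" in table else set(range(4))
    for k, g in enumerate(GROUPS):
        if k not in present:
            continue
        vec = np.zeros(len(names))
        vec[names.index("exposure_10")] = 1.0
        if k < 3 and f"exposure_10:smoking_{GROUPS[k]}" in names:
            vec[names.index(f"exposure_10:smoking_{GROUPS[k]}")] = 1.0
        t = fit.t_test(vec)
        lo, hi = np.ravel(t.conf_int())
        out.append(
            EffectEstimate(
                group=g,
                beta_per_10min=float(np.ravel(t.effect)[0]),
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=float(np.ravel(t.pvalue)[0]),
                p_interaction=p_int,
                n=n,
            )
        )
    return out


def compare_anthropometry(table: pd.DataFrame, outcome: str, exposure: str = "mvpa") -> float:
    """AIC(BMI adjustment) - AIC(height+weight adjustment) for model 1.

    Positive values favour the height+weight parametrization.
    """
    spec = ModelSpec(outcome=outcome, exposure=exposure, adjustment="model1")
    X_hw, y = build_design(table, spec)
    fit_hw = _ols(X_hw, y)

    X_bmi = X_hw.drop(columns=["height_cm", "weight_kg"]).copy()
    height_m = X_hw["height_cm"] / 100.0
    X_bmi["bmi"] = X_hw["weight_kg"] / height_m**2
    fit_bmi = _ols(X_bmi, y)
    return float(fit_bmi.aic - fit_hw.aic)


def sensitivity_exclude_respiratory(table: pd.DataFrame, spec: ModelSpec) -> dict:
    """Requested model on all participants and excluding respiratory disease."""
    full = fit_activity_model(table, spec)
    spec_ex = ModelSpec(
        spec.outcome, spec.exposure, spec.adjustment,
        spec.interaction_with_smoking, exclude_respiratory=True,
    )
    n_flagged = int((table["respiratory_disease"] == 1).sum())
    sub = table[table["respiratory_disease"] == 0]
    if sub.empty:
        return {"all": full, "excluded": None, "n_excluded": n_flagged}
    excluded = fit_activity_model(table, spec_ex)
    return {"all": full, "excluded": excluded, "n_excluded": n_flagged}


def table2(table: pd.DataFrame, outcomes=("fvc", "fev1"),
           exposures=("sedentary", "light", "mvpa")) -> pd.DataFrame:
    """Assemble a Table-2-shaped results frame: per outcome, exposure and
    adjustment model, the overall and stratum-specific slopes per 10 min."""
    rows = []
    for outcome in outcomes:
        for adjustment in ("model1", "model2"):
            for exposure in exposures:
                overall = fit_activity_model(
                    table, ModelSpec(outcome, exposure, adjustment)
                )[0]
                strata = fit_activity_model(
                    table, ModelSpec(outcome, exposure, adjustment, True)
                )
                for est in [overall] + strata:
                    rows.append(
                        {
                            "outcome": outcome,
                            "adjustment": adjustment,
                            "exposure": exposure,
                            "group": est.group,
                            "beta_per_10min": est.beta_per_10min,
                            "ci_low": est.ci_low,
                            "ci_high": est.ci_high,
                            "p_value": est.p_value,
                            "p_interaction": est.p_interaction,
                            "n": est.n,
                        }
                    )
    return pd.DataFrame(rows)
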