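import numpy as np
import pytest
from scipy.stats import pearsonr

from actispiro.synthetic_cohort import (
    GROUPS,
    CohortConfig,
    PlantedEffect,
    generate_cohort,
    mixture_density_x,
    simulate_fof_design,
)


def fast_config(**kw):
    """1-minute epochs over 4 days: full structure at a fraction of the cost."""
    base = dict(n_participants=30, n_days=4, epoch_seconds=60.0, seed=3,
                group_proportions=(0.25, 0.25, 0.25, 0.25))
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(n_participants=0), "n_participants"),
            (dict(group_proportions=(0.5, 0.5, 0.2, -0.2)), "non-negative"),
            (dict(group_proportions=(0.3, 0.3, 0.3, 0.2)), "sum to 1"),
            (dict(epoch_seconds=7.0), "divide 60"),
            (dict(noise_sd=0.0), "noise_sd"),
        ],
    )
    def test_invalid_rejected_with_field_name(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            fast_config(**kw).validate()


class TestGeneration:
    def test_seed_determinism_byte_identical(self):
        a = generate_cohort(fast_config(n_participants=5))
        b = generate_cohort(fast_config(n_participants=5))
        for att in ("epoch_table", "sleep_log", "spirometry_trials", "covariates"):
            assert getattr(a, att).to_csv(index=False) == getattr(b, att).to_csv(index=False)
        assert a.truth == b.truth

    def test_structural_invariants(self):
        cfg = fast_config()
        cohort = generate_cohort(cfg)
        per_day = cohort.epoch_table.groupby("participant_id")["day_index"].nunique()
        assert (per_day == cfg.n_days).all()
        assert (cohort.epoch_table["acc_g"] >= 0).all()
        t = cohort.spirometry_trials.dropna()
        assert (t["fev1"] <= t["fvc"] + 1e-9).all()
        assert (t[["pef", "fef25", "fef50", "fef75"]].gt(0)).all().all()
        assert set(cohort.truth) >= {"planted_surface", "fvc_true", "noise_sd"}

    def test_some_days_fail_wear_validity(self):
        from actispiro.accelerometry import extract_waking_epochs, validate_days

        cfg = fast_config(n_participants=40, p_invalid_day=0.3, seed=9)
        cohort = generate_cohort(cfg)
        waking = extract_waking_epochs(cohort.epoch_table, cohort.sleep_log, cfg.n_days)
        v = validate_days(waking, cohort.sleep_log, cfg.n_days)
        frac_invalid = 1.0 - v["valid"].mean()
        assert 0.1 < frac_invalid < 0.55

    def test_null_construction_no_group_differences(self):
        cfg = fast_config(
            n_participants=500,
            seed=21,
            planted_surface={g: PlantedEffect(0.10, 0.0) for g in GROUPS},
            planted_scalar_effects={},
        )
        cohort = generate_cohort(cfg)
        best = cohort.spirometry_trials.groupby("participant_id").first()
        df = cohort.covariates.set_index("participant_id").join(best[["fvc"]])
        means = df.groupby("smoking")["fvc"].mean()
        counts = df.groupby("smoking")["fvc"].count()
        pooled_sd = df["fvc"].std()
        for k in range(3):
            z = (means[k] - means[3]) / (pooled_sd * np.sqrt(1 / counts[k] + 1 / counts[3]))
            assert abs(z) < 3.5

    def test_planted_bump_yields_positive_exposure_outcome_correlation(self):
        cfg = fast_config(
            n_participants=500,
            seed=22,
            group_proportions=(1.0, 0.0, 0.0, 0.0),
            planted_surface={
                "current": PlantedEffect(0.08, 3.5),
                **{g: PlantedEffect(0.08, 0.0) for g in GROUPS[1:]},
            },
            planted_scalar_effects={},
        )
        cohort = generate_cohort(cfg)
        # direct correlation oracle on the generated tables
        ep = cohort.epoch_table
        sl = cohort.sleep_log.set_index(["participant_id", "day_index"])
        core = ep[(ep["day_index"] >= 2) & (ep["day_index"] <= cfg.n_days - 1)]
        key = list(zip(core["participant_id"], core["day_index"]))
        wake = sl.loc[key, "wake_onset_s"].to_numpy()
        onset = sl.loc[key, "sleep_onset_s"].to_numpy()
        awake = (core["epoch_start_s"].to_numpy() >= wake) & (
            core["epoch_start_s"].to_numpy() < onset
        )
        above = core[awake & (core["acc_g"] >= 0.08)]
        mins = above.groupby("participant_id").size() * cfg.epoch_seconds / 60.0
        mins = mins / (cfg.n_days - 2)
        best = cohort.spirometry_trials.groupby("participant_id")["fvc"].max()
        ids = best.index
        r, p = pearsonr(mins.reindex(ids).fillna(0.0), best)
        assert r > 0 and p < 1e-4


class TestNullFidelityAndPlantVisibility:
    def test_interaction_pvalues_uniform_under_null(self):
        """With no planted interaction, the 1-df ordinal interaction p-values
        over 200 reduced-n cohorts pass a Kolmogorov-Smirnov uniformity check."""
        from scipy.stats import kstest

        from actispiro.scalar_models import ModelSpec, fit_activity_model
        from actispiro.synthetic_cohort import simulate_scalar_table

        ps = []
        for rep in range(200):
            tab = simulate_scalar_table(300, {g: 10.0 for g in GROUPS},
                                        seed=8000 + rep)
            res = fit_activity_model(
                tab, ModelSpec("fvc", "mvpa", "model1", interaction_with_smoking=True)
            )
            ps.append(res[0].p_interaction)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_effect_three_sigma_detected_with_high_power(self):
        """An exposure effect worth 3 residual SDs per exposure-SD is detected
        at n=500 with power above 0.9."""
        from actispiro.scalar_models import ModelSpec, fit_activity_model
        from actispiro.synthetic_cohort import simulate_scalar_table

        # slope such that slope * sd(mvpa) = 3 * noise_sd (300 ml)
        slope_per_10 = 3 * 300.0 / 36.7 * 10.0
        hits = 0
        reps = 30
        for rep in range(reps):
            tab = simulate_scalar_table(500, {g: slope_per_10 for g in GROUPS},
                                        seed=8500 + rep)
            est = fit_activity_model(tab, ModelSpec("fvc", "mvpa", "model1"))[0]
            hits += est.p_value < 0.05
        assert hits / reps > 0.9


class TestFofSimulator:
    def test_densities_normalized_and_model_literal(self, fof_grids):
        x_grid, t_grid = fof_grids
        b = lambda x: np.where(x >= 0.08, 2.0, 0.0)
        design, truth = simulate_fof_design(50, x_grid, t_grid, {"g": b}, seed=5)
        ints = np.trapezoid(truth["F"], x_grid, axis=1)
        assert np.allclose(ints, 1.0, atol=1e-6)
        assert design["A"].shape == (50, x_grid.size)
        assert design["Y"].shape == (50, t_grid.size)
        # noiseless re-simulation reproduces Y up to the planted noise scale
        d0, _ = simulate_fof_design(50, x_grid, t_grid, {"g": b}, seed=5, noise_sd=1e-9)
        resid = design["Y"] - d0["Y"]
        assert 100.0 < resid[:, -1].std() < 500.0

    def test_mixture_density_x_matches_sampling(self):
        # bin probabilities of the analytic transformed density against a
        # large Monte-Carlo sample from the same mixture
        grid = np.linspace(0, 0.4, 4001)
        f = mixture_density_x(grid, 0.2, np.log(0.012), 0.9, np.log(0.08), 0.8)
        rng = np.random.default_rng(0)
        n = 200_000
        active = rng.random(n) < 0.2
        a = np.where(active, rng.lognormal(np.log(0.08), 0.8, n),
                     rng.lognormal(np.log(0.012), 0.9, n))
        x = np.log1p(a)
        edges = np.linspace(0, 0.4, 41)
        counts, _ = np.histogram(x, bins=edges)
        emp = counts / n
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (f[1:] + f[:-1]) / 2)])
        cdf *= (x <= 0.4).mean() / cdf[-1]
        model = np.diff(np.interp(edges, grid, cdf))
        assert np.max(np.abs(emp - model)) < 0.01
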