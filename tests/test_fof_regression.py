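import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from actispiro.fof_regression import (
    CoefficientSurface,
    FofDesign,
    fit_fof,
    slice_surface,
)
from actispiro.synthetic_cohort import simulate_fof_design


def zero_beta(x):
    return np.zeros_like(x)


class TestSurfaceContainer:
    def _surface(self):
        x = np.linspace(0, 0.3, 20)
        t = np.linspace(0.05, 6, 30)
        beta = np.tile(np.linspace(-1, 1, 20)[:, None], (1, 30))  # constant in t
        se = np.full_like(beta, 0.1)
        p = 2 * norm.sf(np.abs(beta / se))
        return CoefficientSurface("g", x, t, beta, se, p)

    def test_mask_is_exactly_p_below_alpha(self):
        s = self._surface()
        assert np.array_equal(s.mask, s.p < 0.05)

    def test_slice_of_t_constant_surface_is_constant(self):
        s = self._surface()
        s1, s2 = s.slice_at(0.5), s.slice_at(5.0)
        assert np.allclose(s1["beta"], s2["beta"])
        assert np.array_equal(s1["mask"], s1["p"] < 0.05)

    def test_slice_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            slice_surface(self._surface(), 7.5)


class TestFitFof:
    def test_degenerate_single_cell_equals_scalar_ols(self, fof_grids):
        # when all activity mass sits in one grid cell, the surface value at
        # that cell must match the scalar OLS slope of y(t) on the cell mass
        x_grid, t_grid = fof_grids
        rng = np.random.default_rng(0)
        n, j = 200, 17
        a = rng.uniform(5.0, 50.0, n)
        A = np.zeros((n, x_grid.size))
        A[:, j] = a
        w = (x_grid[j + 1] - x_grid[j - 1]) / 2.0
        mass = a * w
        slope_true = 3.0
        Y = 1000.0 + np.outer(mass, np.full(t_grid.size, slope_true))
        Y += rng.normal(0, 0.01, Y.shape)
        Z = pd.DataFrame({"age": rng.normal(0, 5, n)})
        d = FofDesign(A, Y, Z, np.array(["g"] * n), x_grid, t_grid)
        fit = fit_fof(d, n_basis_x=12, n_basis_t=6, lambda_x=1e-8, lambda_t=1e-8)
        beta_cell = fit.surface("g").beta[j, :]
        # scalar OLS slope at each t
        X1 = np.column_stack([np.ones(n), mass, Z["age"]])
        coef = np.linalg.lstsq(X1, Y, rcond=None)[0][1]
        assert np.allclose(beta_cell, coef, rtol=0.01)

    def test_outcome_shift_moves_only_intercept(self, fof_grids):
        x_grid, t_grid = fof_grids
        design, _ = simulate_fof_design(80, x_grid, t_grid, {"g": zero_beta}, seed=3)
        d1 = FofDesign(**design)
        f1 = fit_fof(d1, n_basis_x=10, n_basis_t=6, lambda_x=1.0, lambda_t=1.0)
        design2 = dict(design)
        design2["Y"] = design["Y"] + 500.0
        f2 = fit_fof(FofDesign(**design2), n_basis_x=10, n_basis_t=6,
                     lambda_x=1.0, lambda_t=1.0)
        assert np.allclose(f1.surface("g").beta, f2.surface("g").beta, atol=1e-6)
        g1 = f1.scalar_profile("age")["estimate"]
        g2 = f2.scalar_profile("age")["estimate"]
        assert np.allclose(g1, g2, atol=1e-6)

    def test_constant_scalar_covariate_effect_recovered(self, fof_grids):
        # pointwise bands around a planted constant sex effect; estimates are
        # correlated across t, so coverage is averaged over replicates
        x_grid, t_grid = fof_grids
        coverages = []
        for seed in range(5, 11):
            design, _ = simulate_fof_design(
                400, x_grid, t_grid, {"g": zero_beta}, seed=seed,
                gamma={"age": -25.0, "sex": -500.0, "height_cm": 0.0},
                gamma_profile=np.ones(t_grid.size),
            )
            fit = fit_fof(FofDesign(**design), n_basis_x=10, n_basis_t=8)
            prof = fit.scalar_profile("sex")
            coverages.append(((prof["lo"] <= -500.0) & (-500.0 <= prof["hi"])).mean())
            assert np.max(np.abs(prof["estimate"] + 500.0) / prof["se"]) < 4.0
        assert np.mean(coverages) >= 0.90

    def test_permuted_covariate_bands_cover_zero(self, fof_grids):
        # permutation null: the covariate is generated with zero effect, then
        # shuffled across participants; its bands should cover 0
        x_grid, t_grid = fof_grids
        coverages = []
        for rep in range(40):
            design, _ = simulate_fof_design(
                200, x_grid, t_grid, {"g": zero_beta}, seed=50 + rep,
                gamma={"age": 0.0, "sex": -576.0, "height_cm": 32.0},
            )
            rng = np.random.default_rng(rep)
            design["Z"] = design["Z"].copy()
            design["Z"]["age"] = rng.permutation(design["Z"]["age"].to_numpy())
            fit = fit_fof(FofDesign(**design), n_basis_x=10, n_basis_t=10)
            prof = fit.scalar_profile("age")
            coverages.append(((prof["lo"] <= 0) & (0 <= prof["hi"])).mean())
        assert np.mean(coverages) >= 0.94

    def test_planted_bump_slice_peak_location(self, fof_grids):
        x_grid, t_grid = fof_grids
        bump = lambda xg, tg: 10.0 * np.outer(
            np.exp(-0.5 * ((xg - 0.12) / 0.07) ** 2),
            np.exp(-0.5 * ((tg - 2.0) / 1.2) ** 2),
        )
        design, _ = simulate_fof_design(
            300, x_grid, t_grid, {"g": zero_beta}, seed=6,
            beta_surface_by_group={"g": bump},
        )
        fit = fit_fof(FofDesign(**design), n_basis_x=15, n_basis_t=10)
        sl = fit.surface("g").slice_at(1.0)
        peak_x = x_grid[np.argmax(sl["beta"])]
        assert abs(peak_x - 0.12) <= 2 * (x_grid[1] - x_grid[0])

    def test_discretization_stability_of_fitted_integral(self):
        # the fitted functional contribution at t=5 should be insensitive to
        # doubling the x-grid resolution
        from actispiro.synthetic_cohort import MixtureParams

        t_grid = np.arange(0.05, 6.001, 0.05)
        j5 = int(np.argmin(np.abs(t_grid - 5.0)))
        x_fine = np.linspace(0, 0.30, 79)
        # densities must be resolved on BOTH grids for the comparison to be
        # about the estimator; use mixtures without the sharp sedentary spike
        smooth = {"g": MixtureParams(w_active=0.35, mu_sed=np.log(0.04),
                                     sigma_sed=0.5, mu_act=np.log(0.12),
                                     sigma_act=0.6)}
        design, _ = simulate_fof_design(
            200, x_fine, t_grid,
            {"g": lambda x: np.where(x >= 0.08, 2.0, 0.0)}, seed=9,
            mixtures=smooth,
        )
        contrib = {}
        for m, (xg, A) in {
            79: (x_fine, design["A"]),
            40: (x_fine[::2], design["A"][:, ::2]),  # same data, coarser grid
        }.items():
            d = FofDesign(A, design["Y"], design["Z"], design["group"], xg, t_grid)
            fit = fit_fof(d, n_basis_x=12, n_basis_t=8, lambda_x=1.0, lambda_t=1.0)
            beta5 = fit.surface("g").beta[:, j5]
            contrib[m] = np.trapezoid(A * beta5[None, :], xg, axis=1)
        rms = np.sqrt(np.mean((contrib[40] - contrib[79]) ** 2))
        scale = np.sqrt(np.mean((contrib[79] - contrib[79].mean()) ** 2))
        assert rms / scale < 0.01

    def test_small_group_skipped_with_warning(self, fof_grids):
        x_grid, t_grid = fof_grids
        design, _ = simulate_fof_design(
            120, x_grid, t_grid, {"a": zero_beta, "b": zero_beta},
            seed=12, group_probs={"a": 0.95, "b": 0.05},
        )
        with pytest.warns(UserWarning, match="not fitted"):
            fit = fit_fof(FofDesign(**design), n_basis_x=15, n_basis_t=6,
                          lambda_x=1.0, lambda_t=1.0)
        assert fit.group_labels == ["a"]

    def test_misaligned_design_rejected(self, fof_grids):
        x_grid, t_grid = fof_grids
        design, _ = simulate_fof_design(30, x_grid, t_grid, {"g": zero_beta}, seed=13)
        bad = dict(design)
        bad["Y"] = design["Y"][:-1]
        with pytest.raises(ValueError, match="align"):
            fit_fof(FofDesign(**bad), n_basis_x=10, n_basis_t=6)
        bad2 = dict(design)
        bad2["Y"] = np.where(np.arange(design["Y"].size).reshape(design["Y"].shape) == 0,
                             np.nan, design["Y"])
        with pytest.raises(ValueError, match="non-finite"):
            fit_fof(FofDesign(**bad2), n_basis_x=10, n_basis_t=6)
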