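"""c(s) fitting: hydrodynamic conversions, linear subproblem, distributions."""

import numpy as np
import pytest
from scipy.optimize import lsq_linear

from fdsvel import (
    CellModel,
    CsFit,
    CsModel,
    NonlinearityParams,
    SolutionConditions,
    default_fit_range,
    diffusion_from_ff0,
    fit_cs,
    integrate_cs,
    svedberg_mass,
)
from fdsvel.boundary_fit import select_regularization, solve_linear_subproblem


class TestHydrodynamics:
    def test_diffusion_monotone_vanishing_with_ff0(self, conditions):
        s = 2.584e-13
        ds = [diffusion_from_ff0(s, f, conditions) for f in (1.0, 1.4, 2.5, 10.0, 100.0)]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        assert ds[-1] < 1e-7

    def test_diffusion_scales_as_inverse_sqrt_s(self, conditions):
        d1 = diffusion_from_ff0(1e-13, 1.4, conditions)
        d4 = diffusion_from_ff0(4e-13, 1.4, conditions)
        assert d4 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_egfp_mass_self_consistency(self, conditions):
        """s = 2.584 S with f/f0 = 1.39 implies a ~31-35 kDa protein."""
        s = 2.584e-13
        D = diffusion_from_ff0(s, 1.39, conditions)
        mw = svedberg_mass(s, D, conditions)
        assert 31.0 < mw < 35.0

    def test_doubling_d_halves_mass(self, conditions):
        s = 2.5e-13
        m1 = svedberg_mass(s, 6e-7, conditions)
        m2 = svedberg_mass(s, 1.2e-6, conditions)
        assert m2 == pytest.approx(m1 / 2.0, rel=1e-12)

    def test_neutral_buoyancy_rejected(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cond = SolutionConditions(vbar=1.1, density=1.0)
        with pytest.raises(ValueError):
            diffusion_from_ff0(2e-13, 1.4, cond)


def _random_problem(seed=42, n_s=5, n_t=5, n_r=50):
    rng = np.random.default_rng(seed)
    basis = rng.random((n_s, n_t, n_r))
    c_true = np.array([0.0, 2.0, 0.0, 1.5, 0.3])[:n_s]
    ti = rng.normal(0, 1, n_r)
    ri = rng.normal(0, 1, n_t)
    Y = (
        np.tensordot(c_true, basis, 1)
        + ti[None, :]
        + ri[:, None]
        + 0.05 * rng.normal(size=(n_t, n_r))
    )
    return Y, basis, c_true, ti, ri


class TestLinearSubproblem:
    def test_matches_dense_normal_equations_oracle(self):
        """Projection + NNLS equals a brute-force joint bounded solve."""
        Y, basis, *_ = _random_problem()
        n_s, n_t, n_r = basis.shape
        res = solve_linear_subproblem(Y, basis, 0.0, fit_ti=True, fit_ri=True)

        A = np.zeros((n_t * n_r, n_s + n_r + n_t))
        for k in range(n_s):
            A[:, k] = basis[k].ravel()
        for j in range(n_r):
            A[:, n_s + j] = np.tile(np.eye(n_r)[j], n_t)
        for i in range(n_t):
            A[:, n_s + n_r + i] = np.repeat(np.eye(n_t)[i], n_r)
        lb = np.concatenate([np.zeros(n_s), -np.inf * np.ones(n_r + n_t)])
        sol = lsq_linear(A, Y.ravel(), bounds=(lb, np.inf), tol=1e-14)
        fit_oracle = (A @ sol.x).reshape(n_t, n_r)
        rmsd_oracle = np.sqrt(np.mean((Y - fit_oracle) ** 2))

        np.testing.assert_allclose(res.amplitudes, sol.x[:n_s], atol=1e-8)
        fitted = res.model + res.ti[None, :] + res.ri[:, None]
        np.testing.assert_allclose(fitted, fit_oracle, atol=1e-8)
        assert res.rmsd == pytest.approx(rmsd_oracle, abs=1e-8)

    def test_exact_recovery_with_known_ti(self):
        Y, basis, c_true, ti, _ = _random_problem(seed=7)
        rng = np.random.default_rng(8)
        Y = np.tensordot(c_true, basis, 1) + ti[None, :]  # noise-free
        res = solve_linear_subproblem(Y, basis, 0.0, fit_ti=True, fit_ri=False)
        fitted = res.model + res.ti[None, :]
        np.testing.assert_allclose(fitted, Y, atol=1e-8)
        assert res.rmsd < 1e-8

    def test_ti_ri_invariance(self):
        """Adding arbitrary TI and RI fields changes nothing fitted."""
        Y, basis, *_ = _random_problem(seed=3)
        n_s, n_t, n_r = basis.shape
        res1 = solve_linear_subproblem(Y, basis, 0.0, True, True)
        Y2 = Y + 11.0 * np.sin(np.arange(n_r))[None, :] + 4.2 * np.arange(n_t)[:, None]
        res2 = solve_linear_subproblem(Y2, basis, 0.0, True, True)
        np.testing.assert_allclose(res1.amplitudes, res2.amplitudes, atol=1e-8)
        assert abs(res1.rmsd - res2.rmsd) < 1e-8

    def test_regularization_smooths_monotonically(self):
        Y, basis, *_ = _random_problem(seed=9)
        prev = np.inf
        for alpha in (0.0, 1e-3, 1e-1, 1e1, 1e3):
            res = solve_linear_subproblem(Y, basis, alpha, True, True)
            pen = np.linalg.norm(np.diff(res.amplitudes, 2))
            assert pen <= prev + 1e-10
            prev = pen

    def test_fratio_selection_hits_confidence_band(self):
        Y, basis, *_ = _random_problem(seed=11, n_t=8, n_r=60)
        alpha = select_regularization(Y, basis, True, True)
        assert alpha > 0
        chi0 = solve_linear_subproblem(Y, basis, 0.0, True, True).rmsd ** 2
        chia = solve_linear_subproblem(Y, basis, alpha, True, True).rmsd ** 2
        # smoothed solution stays within ~ the one-sigma F-ratio band
        assert chia < chi0 * 1.2


class TestIntegrateCs:
    def test_single_point_sw(self):
        s = np.linspace(1, 5, 9)
        c = np.zeros(9)
        c[4] = 3.0
        s_w, amp = integrate_cs(CsModel(s_grid=s, ff0=1.4, amplitudes=c))
        assert s_w == pytest.approx(3.0)
        assert amp > 0

    def test_symmetric_two_peak_average(self):
        s = np.linspace(1, 5, 41)
        c = np.zeros(41)
        c[10] = c[30] = 2.0  # equal areas at s1, s2
        s_w, _ = integrate_cs(CsModel(s_grid=s, ff0=1.4, amplitudes=c))
        assert s_w == pytest.approx((s[10] + s[30]) / 2.0)

    def test_quadrature_matches_dense_oracle(self):
        rng = np.random.default_rng(13)
        s = np.linspace(0.5, 6, 23)
        c = rng.random(23)
        s_w, amp = integrate_cs(CsModel(s_grid=s, ff0=1.4, amplitudes=c))
        from scipy.integrate import simpson

        s_fine = np.linspace(s[0], s[-1], 23 * 64 - 63)
        c_fine = np.interp(s_fine, s, c)
        amp_o = simpson(c_fine, x=s_fine)
        sw_o = simpson(s_fine * c_fine, x=s_fine) / amp_o
        assert amp == pytest.approx(amp_o, abs=1e-10)
        assert s_w == pytest.approx(sw_o, abs=1e-10)

    def test_zero_integral_flagged(self):
        s = np.linspace(1, 5, 9)
        with pytest.warns(UserWarning, match="undefined"):
            s_w, amp = integrate_cs(CsModel(s_grid=s, ff0=1.4, amplitudes=np.zeros(9)))
        assert np.isnan(s_w) and amp == 0.0

    def test_subrange_integration(self):
        s = np.linspace(1, 5, 41)
        c = np.zeros(41)
        c[10] = c[30] = 2.0
        s_w, _ = integrate_cs(CsModel(s_grid=s, ff0=1.4, amplitudes=c), 1.0, 3.0)
        assert s_w == pytest.approx(s[10])


class TestFitRange:
    def test_zero_delta_full_column(self, egfp_cell):
        assert default_fit_range(egfp_cell, 0.0) == (6.0, 7.2)

    def test_meniscus_exclusion_rule(self, egfp_cell):
        """Excludes data closer to the meniscus than the cone diameter."""
        r_min, r_max = default_fit_range(egfp_cell, 0.15)
        assert r_min == pytest.approx(6.30)
        assert r_max == 7.2

    def test_monotone_in_delta(self, egfp_cell):
        r1, _ = default_fit_range(egfp_cell, 0.05)
        r2, _ = default_fit_range(egfp_cell, 0.10)
        assert r2 > r1

    def test_empty_range_rejected(self, egfp_cell):
        with pytest.raises(ValueError):
            default_fit_range(egfp_cell, 0.7)


class TestCsFit:
    def test_noise_free_single_species_exact(self, tiny_sim, egfp_cell):
        """With the true f/f0 fixed, a species on the grid refits exactly."""
        s_grid, s_true, spec, sim = tiny_sim
        res = CsFit(
            sim.scansets[1],
            egfp_cell,
            s_grid=s_grid,
            ff0=1.39,
            float_params=(),
            fit_ti=True,
            reg_alpha=0.0,
            n_grid=400,
        ).fit()
        assert res.rmsd < 1e-6 * 50.0
        assert abs(res.s_w - s_true) < (s_grid[1] - s_grid[0])
        assert res.boundary_amplitude == pytest.approx(50.0, rel=1e-6)

    def test_noise_free_ff0_refinement(self, tiny_sim, egfp_cell):
        s_grid, s_true, spec, sim = tiny_sim
        res = CsFit(
            sim.scansets[1],
            egfp_cell,
            s_grid=s_grid,
            ff0=1.25,
            float_params=("ff0",),
            fit_ti=True,
            reg_alpha=0.0,
            n_grid=400,
        ).fit()
        assert res.ff0 == pytest.approx(1.39, rel=0.01)
        assert abs(res.s_w - s_true) < (s_grid[1] - s_grid[0])

    def test_linear_path_bit_identical_to_unit_kappa(self, tiny_sim, egfp_cell):
        """kappa = 1, a0 = 0 must reproduce the plain linear analysis exactly."""
        s_grid, _, _, sim = tiny_sim
        kwargs = dict(
            s_grid=s_grid, ff0=1.39, float_params=(), fit_ti=True,
            reg_alpha=0.0, n_grid=400,
        )
        r_lin = CsFit(sim.scansets[1], egfp_cell, **kwargs).fit()
        r_nl = CsFit(
            sim.scansets[1],
            egfp_cell,
            nonlinearity=NonlinearityParams(a0=0.0, kappa=1.0),
            **kwargs,
        ).fit()
        assert r_nl.rmsd == r_lin.rmsd
        np.testing.assert_array_equal(r_nl.cs.amplitudes, r_lin.cs.amplitudes)
        np.testing.assert_array_equal(r_nl.residuals, r_lin.residuals)

    def test_few_scans_drift_warns(self, tiny_sim, egfp_cell):
        s_grid, _, _, sim = tiny_sim
        from fdsvel import ScanSet

        short = ScanSet(scans=sim.scansets[1].scans[:5])
        with pytest.warns(UserWarning, match="weakly identified"):
            CsFit(
                short,
                egfp_cell,
                s_grid=s_grid,
                float_params=("ff0", "de_dt"),
                n_grid=300,
            )

    def test_summary_and_report(self, tiny_sim, egfp_cell):
        s_grid, _, _, sim = tiny_sim
        res = CsFit(
            sim.scansets[1], egfp_cell, s_grid=s_grid, ff0=1.39,
            float_params=(), fit_ti=True, reg_alpha=0.0, n_grid=400,
        ).fit()
        text = res.summary()
        assert "s_w" in text and "f/f0" in text
        rep = res.report(run_id="unit")
        assert rep.run_id == "unit"
        assert rep.s_w == res.s_w

    def test_fit_cs_wrapper(self, tiny_sim, egfp_cell):
        s_grid, s_true, _, sim = tiny_sim
        rep = fit_cs(
            sim.scansets[1], egfp_cell, s_grid=s_grid, ff0=1.39,
            float_params=(), fit_ti=True, reg_alpha=0.0, n_grid=400,
        )
        assert abs(rep.s_w - s_true) < (s_grid[1] - s_grid[0])
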