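"""Inner-loop fit: initialization lookup, weighted objective, recovery, statistics."""

import numpy as np
import pytest

from spmekin import FitConfig, KineticParams, net_conc
from spmekin.fitting import (
    fit_replicate,
    initial_params,
    initial_tau_range,
    rmse,
    rsd,
    weighted_objective,
)
from spmekin.profiles import ExtractionProfile

from conftest import make_profile


class TestInitialTauRange:
    @pytest.mark.parametrize(
        "t_max,expected",
        [(10.0, (4.0, 9.0)), (60.0, (30.0, 40.0)), (4.0, (1.0, 3.0)),
         (20.0, (9.0, 14.0)), (90.0, (45.0, 80.0)), (300.0, (100.0, 370.0))],
    )
    def test_tabulated_rows(self, t_max, expected):
        assert initial_tau_range(t_max) == pytest.approx(expected)

    def test_interpolation_between_rows(self):
        lo, hi = initial_tau_range(15.0)
        assert 4.0 < lo < 9.0 and 9.0 < hi < 14.0
        assert lo == pytest.approx((4 + 9) / 2)
        assert hi == pytest.approx((9 + 14) / 2)

    def test_clamped_outside_table(self):
        assert initial_tau_range(1.0) == (1.0, 3.0)
        assert initial_tau_range(5000.0) == (100.0, 370.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            initial_tau_range(0.0)


class _FixedRng:
    """Stub generator returning prescribed uniform draws."""

    def __init__(self, scalar, pair):
        self.scalar, self.pair = scalar, pair

    def uniform(self, lo, hi, size=None):
        if size is None:
            return self.scalar
        return np.array(self.pair)


class TestInitialParams:
    def test_plateau_matched_arithmetic(self, noise_free_profile):
        cfg = FitConfig(seed=0)
        rng = _FixedRng(100.0, (8.0, 12.0))
        p = initial_params(noise_free_profile, cfg, rng)
        c_last = noise_free_profile.areas[-1]
        assert p.k1 == pytest.approx(100.0 * c_last)
        assert p.k1 - p.k2 == pytest.approx(c_last)
        assert p.tau1 < p.tau2

    def test_tau_draws_inside_lookup_range(self):
        # observed peak exactly at t=20 -> tau range (9, 14)
        prof = ExtractionProfile(
            "e", "c", 1, np.array([5.0, 10, 15, 20, 30, 45, 60]),
            np.array([0.3, 0.6, 0.9, 1.2, 1.1, 1.05, 1.0]),
        )
        cfg = FitConfig(seed=0)
        rng = np.random.default_rng(5)
        lo, hi = initial_tau_range(20.0)
        assert (lo, hi) == (9.0, 14.0)
        for _ in range(50):
            p = initial_params(prof, cfg, rng)
            assert lo <= p.tau1 <= hi
            assert p.tau1 < p.tau2 <= hi * cfg.tau_ratio_max

    def test_deterministic_given_seed(self, noise_free_profile):
        cfg = FitConfig(seed=0)
        a = initial_params(noise_free_profile, cfg, np.random.default_rng(9))
        b = initial_params(noise_free_profile, cfg, np.random.default_rng(9))
        assert a == b


class TestWeightedObjective:
    def test_exact_fit_is_zero(self, toy_params, toy_grid):
        prof = make_profile(toy_params, toy_grid)
        for W in (1.0, 10.0, 500.0):
            assert weighted_objective(toy_params, prof, W) == pytest.approx(0.0)

    def test_w1_reduces_to_sse(self, toy_params, toy_grid):
        prof = make_profile(toy_params, toy_grid)
        other = KineticParams(2.2, 1.1, 11.0, 21.0)
        sse = float(np.sum((net_conc(other, toy_grid) - prof.areas) ** 2))
        assert weighted_objective(other, prof, 1.0) == pytest.approx(sse)

    def test_two_point_toy_arithmetic(self):
        # data [1.0 (peak), 0.5]; model [1.1, 0.5]; W=10 weights only the
        # peak sample: 10 * 0.1^2 + 0 = 0.1
        prof = ExtractionProfile("t", "c", 1, np.array([10.0, 60.0]),
                                 np.array([1.0, 0.5]))
        w10 = weighted_objective_direct(prof, np.array([1.1, 0.5]), 10.0)
        assert w10 == pytest.approx(10 * 0.01)

    def test_w_below_one_rejected(self, toy_params, toy_grid):
        prof = make_profile(toy_params, toy_grid)
        with pytest.raises(ValueError):
            weighted_objective(toy_params, prof, 0.5)


def weighted_objective_direct(profile, model_values, W):
    y = profile.fitting_areas
    w = np.ones(len(y))
    w[int(np.argmax(y))] = W
    return float(np.sum(w * (model_values - y) ** 2))


class TestStatistics:
    def test_rmse(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([0.1, -0.1], [0.0, 0.0]) == pytest.approx(0.1)
        assert rmse([0.3, 0, 0], [0, 0, 0]) == pytest.approx(0.1732, abs=1e-4)
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    def test_rsd(self):
        assert rsd([1.0, 1.0, 1.0]) == 0.0
        assert rsd([9.0, 10.0, 11.0]) == pytest.approx(10.0)
        assert rsd([47.96, 47.96, 47.96]) == pytest.approx(0.0, abs=1e-10)
        with pytest.raises(ValueError):
            rsd([1.0])
        with pytest.raises(ValueError):
            rsd([-1.0, 1.0])


class TestFitReplicate:
    def test_noise_free_recovery(self, toy_params, toy_grid, identifiable_config):
        prof = make_profile(toy_params, toy_grid)
        fit = fit_replicate(prof, 1.0, identifiable_config)
        for name in ("k1", "k2", "tau1", "tau2"):
            est, true = getattr(fit.params, name), getattr(toy_params, name)
            assert est == pytest.approx(true, rel=1e-3), name
        assert fit.objective < 1e-12
        assert fit.converged
        assert not fit.diagnostics["gauge_adopted"]

    def test_noisy_rmse_at_noise_scale(self, toy_params, toy_grid,
                                       identifiable_config):
        rng = np.random.default_rng(21)
        prof = make_profile(toy_params, toy_grid, noise=0.03, rng=rng)
        fit = fit_replicate(prof, 1.0, identifiable_config)
        assert 0.005 < fit.rmse < 0.06

    def test_requires_five_points(self, toy_params, identifiable_config):
        prof = make_profile(toy_params, np.array([2.0, 10, 30, 60]))
        with pytest.raises(ValueError, match="at least 5"):
            fit_replicate(prof, 1.0, identifiable_config)

    def test_monotone_profile_flagged(self, identifiable_config):
        # pure rise to plateau: observed peak at the last sample
        p = KineticParams(1.05, 0.05, 10.0, 2000.0, validate=False)
        grid = np.array([2.0, 5, 10, 20, 30, 45, 60])
        y = net_conc(p, grid)
        prof = ExtractionProfile("m", "c", 1, grid, y)
        fit = fit_replicate(prof, 1.0, identifiable_config)
        assert fit.diagnostics["no_interior_peak"]

    def test_deterministic_given_seed(self, toy_params, toy_grid,
                                      identifiable_config):
        rng = np.random.default_rng(3)
        prof = make_profile(toy_params, toy_grid, noise=0.03, rng=rng)
        f1 = fit_replicate(prof, 10.0, identifiable_config)
        f2 = fit_replicate(prof, 10.0, identifiable_config)
        assert f1.params == f2.params
        assert f1.objective == f2.objective

    def test_scale_equivariance(self, toy_params, toy_grid, identifiable_config):
        rng = np.random.default_rng(8)
        prof = make_profile(toy_params, toy_grid, noise=0.02, rng=rng)
        scaled = ExtractionProfile(
            prof.compound, prof.condition, prof.replicate_id,
            prof.times, prof.areas * 3.7e8,
        )
        f1 = fit_replicate(prof, 5.0, identifiable_config)
        f2 = fit_replicate(scaled, 5.0, identifiable_config)
        assert f2.params.k1 / f1.params.k1 == pytest.approx(3.7e8, rel=1e-6)
        assert f2.params.k2 / f1.params.k2 == pytest.approx(3.7e8, rel=1e-6)
        assert f2.params.tau1 == pytest.approx(f1.params.tau1, rel=1e-6)
        assert f2.params.tau2 == pytest.approx(f1.params.tau2, rel=1e-6)

    def test_noise_free_recovery_random_params(self, identifiable_config):
        """W=1 noise-free fits recover identifiable truths to optimizer tolerance.

        Truths are drawn inside the model's target regime: time constants
        consistent with the peak-time initialization lookup (as for real
        overshoot profiles), moderate amplitudes so every parameter is
        identifiable.
        """
        from spmekin.fitting import initial_tau_range
        from spmekin.kinetics import peak_time

        rng = np.random.default_rng(17)
        found = 0
        while found < 15:
            k2 = rng.uniform(0.5, 4.0)
            c_inf = rng.uniform(0.5, 2.0)
            tau1 = rng.uniform(5.0, 40.0)
            tau2 = tau1 * rng.uniform(1.3, 3.0)
            truth = KineticParams(k2 + c_inf, k2, tau1, tau2)
            t_max = peak_time(truth)
            lo, hi = initial_tau_range(t_max)
            if not (0.55 * lo <= tau1 and tau2 <= 1.9 * hi):
                continue  # outside the lookup's regime; not a realistic profile
            found += 1
            t_end = max(4 * tau2, 1.5 * t_max)
            grid = np.geomspace(t_end / 50, t_end, 12)
            prof = make_profile(truth, grid)
            fit = fit_replicate(prof, 1.0, identifiable_config)
            np.testing.assert_allclose(
                fit.params.as_array(), truth.as_array(), rtol=2e-3,
                err_msg=f"truth={truth}",
            )

    def test_peak_residual_monotone_in_w(self, octanoate_params):
        """Raising W never worsens the squared residual at the peak sample."""
        from spmekin.simulate import SimScenario, generate_replicates
        from spmekin.profiles import normalize_profile

        sc = SimScenario(name="w-mono", true_params=octanoate_params, seed=5)
        prof = normalize_profile(generate_replicates(sc).profiles[0])
        cfg = FitConfig(seed=5)
        prev = None
        for W in (1.0, 10.0, 100.0, 1000.0):
            fit = fit_replicate(prof, W, cfg)
            t, y = prof.fitting_times, prof.fitting_areas
            i = int(np.argmax(y))
            r2 = float((net_conc(fit.params, t[i]) - y[i]) ** 2)
            if prev is not None:
                assert r2 <= prev * (1 + 1e-6) + 1e-12
            prev = r2
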