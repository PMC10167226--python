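"""Integrated rate law, sigmoid fits and the constrained global fit."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

import loopchap as lc
from loopchap.kinetics import _mass_fraction_lam_kap, sigmoid
from loopchap.plateio import group_traces, traces_from_plate

from conftest import random_valid_params

AB42 = lc.KineticParams(k_n=4.6e-5, k_plus=3e6, k_2=6.2e3)


def ode_mass_fraction(p, times):
    """Independent oracle: numerical integration of the moment equations."""
    def rhs(_, y):
        P, M = y
        m = max(p.m0 - M, 0.0)
        return [p.k_n * m**p.n_c + p.k_2 * m**p.n_2 * M, 2 * p.k_plus * m * P]

    sol = solve_ivp(rhs, (0.0, times[-1]), [0.0, 0.0], t_eval=times,
                    rtol=1e-9, atol=1e-15, method="LSODA")
    return sol.y[1] / p.m0


def halftime(times, mass):
    return float(np.interp(0.5, mass, times))


class TestKineticCoeffs:
    def test_lambda_zero_algebraic_limit(self):
        p = lc.KineticParams(k_n=0.0, k_plus=3e6, k_2=6.2e3)
        c = lc.kinetic_coeffs(p)
        assert c.c_plus == 0.0 and c.c_minus == 0.0
        assert c.k_inf_tilde == pytest.approx(c.k_inf)
        assert c.b_minus == pytest.approx(0.0)

    def test_coefficient_identity(self):
        """k̃∞² − k∞² = λ⁴/κ² (equivalently −4 C₊C₋κ² = λ⁴/κ²)."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_valid_params(rng)
            c = lc.kinetic_coeffs(p)
            assert c.k_inf_tilde**2 - c.k_inf**2 == \
                pytest.approx(c.lam**4 / c.kappa**2, rel=1e-9)

    def test_against_high_precision_evaluation(self):
        """Representative parameters: coefficients match 50-digit arithmetic."""
        mp = pytest.importorskip("mpmath")
        mp.mp.dps = 50
        p = AB42
        lam, kap = mp.mpf(p.lam), mp.mpf(p.kappa)
        k_inf = mp.sqrt(2 * kap**2 / 6 + lam**2)  # n_c = n_2 = 2
        k_til = mp.sqrt(k_inf**2 + lam**4 / kap**2)
        c = lc.kinetic_coeffs(p)
        assert c.k_inf == pytest.approx(float(k_inf), rel=1e-12)
        assert c.k_inf_tilde == pytest.approx(float(k_til), rel=1e-12)
        assert c.b_plus == pytest.approx(float((k_inf + k_til) / (2 * kap)), rel=1e-12)

    def test_kappa_zero_rejected(self):
        p = lc.KineticParams(k_n=1e-4, k_plus=3e6, k_2=0.0)
        with pytest.raises(lc.LoopchapError, match="kappa"):
            lc.kinetic_coeffs(p)


class TestMassFraction:
    def test_boundary_identities(self):
        t = np.array([0.0, 1e7])
        m = lc.simulate_mass_fraction(AB42, t)
        assert m[0] == pytest.approx(0.0, abs=1e-12)
        assert m[1] == pytest.approx(1.0, abs=1e-9)

    def test_unseeded_no_primary_nucleation_stays_zero(self):
        p = lc.KineticParams(k_n=0.0, k_plus=3e6, k_2=6.2e3)
        m = lc.simulate_mass_fraction(p, np.linspace(0, 1e6, 50))
        assert np.all(m == 0.0)

    def test_values_bounded_and_nondecreasing(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            p = random_valid_params(rng, ratio_decades=(-3.0, 0.0))
            t = np.linspace(0, 50 / p.kappa, 400)
            m = lc.simulate_mass_fraction(p, t)
            assert np.all(m >= -1e-12) and np.all(m <= 1.0 + 1e-12)
            assert np.all(np.diff(m) >= -1e-10)

    def test_overflow_safe_at_extreme_kappa_t(self):
        t = np.array([0.0, 1e9])  # kappa*t ~ 1e6: naive exp would overflow
        m = lc.simulate_mass_fraction(AB42, t)
        assert np.isfinite(m).all() and m[1] == pytest.approx(1.0)

    def test_primary_only_branch_is_kappa_to_zero_limit(self):
        lam = 1e-4
        t = np.linspace(0, 1e5, 200)
        limit = _mass_fraction_lam_kap(t, lam, 0.0, 2.0, 2.0)
        near = _mass_fraction_lam_kap(t, lam, 1e-7, 2.0, 2.0)
        assert np.allclose(limit, near, atol=1e-6)

    def test_halftime_agrees_with_ode_oracle_at_reference_params(self):
        """κ⁻¹ ≈ 1 h, m0 = 3 µM, n_c = n_2 = 2: agreement within 5%."""
        p = lc.KineticParams(k_n=3.6e-6, k_plus=3e6, k_2=476.0)
        assert p.kappa == pytest.approx(1 / 3600.0, rel=0.01)
        t = np.linspace(0, 1.5e5, 3000)
        h_cf = halftime(t, lc.simulate_mass_fraction(p, t))
        h_ode = halftime(t, ode_mass_fraction(p, t))
        assert abs(h_cf - h_ode) / h_ode < 0.05

    def test_halftime_monotone_in_each_rate_constant(self):
        """Speeding up any microscopic step never slows aggregation."""
        t = np.linspace(0, 3e5, 1500)
        base = halftime(t, lc.simulate_mass_fraction(AB42, t))
        from dataclasses import replace
        for key in ("k_n", "k_plus", "k_2"):
            faster = replace(AB42, **{key: getattr(AB42, key) * 4})
            slower = replace(AB42, **{key: getattr(AB42, key) / 4})
            assert halftime(t, lc.simulate_mass_fraction(faster, t)) <= base
            assert halftime(t, lc.simulate_mass_fraction(slower, t)) >= base

    def test_negative_times_rejected(self):
        with pytest.raises(lc.LoopchapError):
            lc.simulate_mass_fraction(AB42, np.array([-1.0, 0.0, 1.0]))


class TestSigmoidFit:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 10000, 300)
        y = sigmoid(t, 0.0, 1.0, 0.01, 5000.0)
        f = lc.fit_sigmoid((t, y))
        assert f.f0 == pytest.approx(0.0, abs=1e-6)
        assert f.amplitude == pytest.approx(1.0, rel=1e-3)
        assert f.r_max == pytest.approx(0.01, rel=1e-3)
        assert f.tau_half == pytest.approx(5000.0, rel=1e-3)
        assert f.tau_in_range

    def test_halftime_property_of_fitted_curve(self):
        t = np.linspace(0, 10000, 300)
        y = sigmoid(t, 0.2, 0.8, 0.005, 4000.0)
        f = lc.fit_sigmoid((t, y))
        assert f(f.tau_half) == pytest.approx(f.f0 + f.amplitude / 2)

    def test_monotone_decreasing_trace_fails(self):
        t = np.linspace(0, 100, 50)
        with pytest.raises(lc.FitConvergenceError):
            lc.fit_sigmoid((t, 1.0 - t / 100.0))

    def test_noisy_halftime_recovery_median_under_2pct(self):
        rng = np.random.default_rng(21)
        t = np.linspace(0, 10000, 120)
        errs = []
        for _ in range(100):
            y = sigmoid(t, 0.0, 1.0, 0.01, 5000.0) + rng.normal(0, 0.02, t.size)
            f = lc.fit_sigmoid((t, y))
            errs.append(abs(f.tau_half - 5000.0) / 5000.0)
        assert np.median(errs) < 0.02


class TestNormalizeTht:
    def test_single_clean_sigmoid_maps_to_unit_logistic(self):
        t = np.linspace(0, 10000, 200)
        tr = lc.AggregationTrace(times=t, signal=sigmoid(t, 50.0, 900.0, 0.01, 5000.0),
                                 substrate="Ab42")
        nt = lc.normalize_tht([tr])
        assert not nt.fallback_used
        assert np.allclose(nt.signal, sigmoid(t, 0.0, 1.0, 0.01, 5000.0), atol=1e-6)

    def test_identical_replicates_average_to_one(self):
        t = np.linspace(0, 10000, 200)
        tr = lc.AggregationTrace(times=t, signal=sigmoid(t, 0.0, 1.0, 0.01, 5000.0),
                                 substrate="Ab42")
        nt4 = lc.normalize_tht([tr] * 4)
        nt1 = lc.normalize_tht([tr])
        assert np.allclose(nt4.signal, nt1.signal)
        assert nt4.n_replicates == 4

    def test_minmax_mode_spans_unit_interval(self):
        t = np.linspace(0, 10000, 200)
        tr = lc.AggregationTrace(times=t, signal=sigmoid(t, 50.0, 900.0, 0.01, 5000.0),
                                 substrate="Ab42")
        nt = lc.normalize_tht([tr], method="minmax")
        assert not nt.fallback_used
        assert nt.signal.min() == pytest.approx(0.0)
        assert nt.signal.max() == pytest.approx(1.0)

    def test_flat_replicate_triggers_fallback(self):
        t = np.linspace(0, 10000, 200)
        flat = lc.AggregationTrace(times=t, signal=np.full(t.size, 5.0),
                                   substrate="Ab42")
        nt = lc.normalize_tht([flat])
        assert nt.fallback_used
        assert np.allclose(nt.signal, 0.0)


class TestHalftimeDelay:
    def _fit(self, tau):
        t = np.linspace(0, 10 * tau, 200)
        return lc.fit_sigmoid((t, sigmoid(t, 0.0, 1.0, 20.0 / tau, tau)))

    def test_identical_conditions_give_unit_ratios(self):
        f = self._fit(5000.0)
        table = lc.halftime_delay({0: f, 50: f, 100: f})
        assert np.allclose(table["tau_rel"], 1.0)

    def test_doubled_halftime_detected(self):
        table = lc.halftime_delay({0: self._fit(5000.0), 100: self._fit(10000.0)})
        assert table.set_index("ratio_pct").loc[100, "tau_rel"] == \
            pytest.approx(2.0, rel=0.02)

    def test_missing_control_is_an_error(self):
        with pytest.raises(lc.LoopchapError, match="control"):
            lc.halftime_delay({50: self._fit(5000.0)})


def tht_panel_curves(seed, **cfg_kw):
    cfg = lc.GeneratorConfig(seed=seed, **cfg_kw)
    plate, wmap, truth = lc.gen_tht_panel(cfg)
    groups = group_traces(traces_from_plate(plate, wmap))
    panel = {float(r): lc.normalize_tht(trs) for (_, r), trs in groups.items()}
    return panel, truth


class TestGlobalFit:
    def test_identical_conditions_give_unit_factors(self):
        t = np.linspace(0, 1.2e5, 150)
        curve = lc.simulate_mass_fraction(AB42, t)
        panel = {r: (t, curve) for r in (0.0, 10.0, 50.0, 100.0)}
        fit = lc.global_fit(panel, "k_2", n_starts=2, seed=0)
        for factor in fit.factors.values():
            assert factor == pytest.approx(1.0, abs=0.02)

    def test_k2_suppression_recovered_and_ranked_first(self):
        panel, truth = tht_panel_curves(seed=42, tht_noise_frac=0.01)
        ranked = lc.rank_global_fits(panel, n_starts=4, seed=0)
        assert ranked[0].free_constant == "k_2"
        assert ranked[0].residual_sum_squares < ranked[1].residual_sum_squares
        for ratio, true_f in truth["factors"].items():
            if ratio == 0.0:
                continue
            assert ranked[0].factors[ratio] == pytest.approx(true_f, rel=0.15)

    def test_kplus_suppression_ranked_first(self):
        panel, _ = tht_panel_curves(seed=43, tht_noise_frac=0.01,
                                    suppression_target="k_plus")
        ranked = lc.rank_global_fits(panel, n_starts=4, seed=0)
        assert ranked[0].free_constant == "k_plus"

    def test_missing_control_condition_is_an_error(self):
        t = np.linspace(0, 1.2e5, 100)
        curve = lc.simulate_mass_fraction(AB42, t)
        with pytest.raises(lc.LoopchapError, match="control"):
            lc.global_fit({50.0: (t, curve)}, "k_2")

    def test_flat_degenerate_panel_is_an_error(self):
        t = np.linspace(0, 1.2e5, 100)
        flat = np.zeros_like(t)
        with pytest.raises(lc.LoopchapError, match="degenerate"):
            lc.global_fit({0.0: (t, flat), 100.0: (t, flat)}, "k_2")

    def test_identifiable_products_exposed(self):
        """On exact mass-fraction curves the rate-constant products are
        recovered sharply (fluorescence normalization adds its own few-%
        distortion, so this uses mass-fraction input directly)."""
        from dataclasses import replace
        t = np.linspace(0, 1.2e5, 150)
        panel = {}
        for ratio, f in [(0.0, 1.0), (50.0, 0.5), (100.0, 0.2)]:
            p = replace(AB42, k_2=AB42.k_2 * f)
            panel[ratio] = (t, lc.simulate_mass_fraction(p, t))
        fit = lc.global_fit(panel, "k_2", n_starts=2, seed=0)
        assert fit.kplus_k2 == pytest.approx(AB42.k_plus * AB42.k_2, rel=0.01)
        assert fit.kplus_kn == pytest.approx(AB42.k_plus * AB42.k_n, rel=0.05)
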