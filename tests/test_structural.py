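"""Structural model: ODE route vs closed forms, AUC, dose nonlinearity."""

import numpy as np
import pytest

from rifpk.structural import (AUCDivergenceError, StructuralParams,
                              StructuralVariant, auc, predict_conc,
                              predict_conc_fast)

BASE = StructuralParams(Tlag=0.340, Tk0=0.460, V=36.2, Vmax=191.0, Km=20.4)
GRID = np.array([0.0, 0.16, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0,
                 9.0, 12.0, 16.0, 24.0])


class TestPredictConc:
    def test_zero_before_lag(self):
        prof = predict_conc(BASE, 600.0, [0.0, 0.1, 0.2, 0.33])
        assert np.all(prof.conc[np.asarray(prof.times) <= BASE.Tlag] == 0.0)

    def test_mass_plateau_without_elimination(self):
        """With elimination off the plateau equals dose/V."""
        p = StructuralParams(Tlag=0.34, Tk0=0.46, V=36.2, Vmax=0.0, Km=20.4)
        prof = predict_conc(p, 600.0, [1.0, 5.0, 24.0])
        assert prof.conc == pytest.approx(600.0 / 36.2, rel=1e-8)

    def test_implicit_mm_decay_relation(self):
        """Post-absorption decay satisfies Km*ln(C1/C2) + (C1-C2) = (Vmax/V)*dt."""
        times = np.array([1.0, 2.0, 4.0, 8.0, 14.0, 20.0])
        conc = predict_conc(BASE, 600.0, times).conc
        for i in range(len(times) - 1):
            lhs = BASE.Km * np.log(conc[i] / conc[i + 1]) + conc[i] - conc[i + 1]
            rhs = BASE.Vmax / BASE.V * (times[i + 1] - times[i])
            assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_fast_route_matches_ode_route(self):
        a = predict_conc(BASE, 600.0, GRID).conc
        b = predict_conc_fast(BASE, 600.0, GRID).conc
        np.testing.assert_allclose(b, a, rtol=1e-6, atol=1e-9)

    def test_scaling_through_dose_over_v(self):
        """The profile depends on (V, Vmax, dose) only through dose/V, Vmax/V."""
        c = 2.7
        scaled = StructuralParams(Tlag=BASE.Tlag, Tk0=BASE.Tk0, V=c * BASE.V,
                                  Vmax=c * BASE.Vmax, Km=BASE.Km)
        a = predict_conc_fast(BASE, 600.0, GRID).conc
        b = predict_conc_fast(scaled, c * 600.0, GRID).conc
        np.testing.assert_allclose(b, a, rtol=1e-9)

    def test_mass_balance(self):
        """Absorbed - eliminated - remaining amount ~ 0 along the profile."""
        t = np.linspace(0, 24, 4001)
        conc = predict_conc_fast(BASE, 600.0, t).conc
        elim_rate = BASE.Vmax * conc / (BASE.Km + conc)
        for t_chk in (1.0, 4.0, 12.0, 24.0):
            k = np.searchsorted(t, t_chk)
            absorbed = 600.0 * np.clip(
                (t_chk - BASE.Tlag) / BASE.Tk0, 0.0, 1.0)
            eliminated = np.trapezoid(elim_rate[: k + 1], t[: k + 1])
            remaining = conc[k] * BASE.V
            assert absorbed - eliminated - remaining == pytest.approx(
                0.0, abs=0.02 * 600.0 * 1e-2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            predict_conc(BASE, 0.0, [1.0])
        with pytest.raises(ValueError):
            predict_conc(BASE, 600.0, [-1.0])
        with pytest.raises(ValueError):
            StructuralParams(Tlag=0.0, Tk0=0.46, V=36.2, Vmax=191.0, Km=20.4)


class TestAUC:
    def test_matches_brute_force_riemann(self):
        """AUC(0-inf) against fine-step Riemann integration (0.1% oracle)."""
        val = auc(BASE, 600.0)
        t = np.arange(0.0, 400.0, 1e-3)
        brute = np.trapezoid(predict_conc_fast(BASE, 600.0, t).conc, t)
        assert val == pytest.approx(brute, rel=1e-3)

    def test_partial_auc_matches_brute_force(self):
        val = auc(BASE, 600.0, t_end=24.0)
        t = np.arange(0.0, 24.0 + 1e-3, 1e-3)
        brute = np.trapezoid(predict_conc_fast(BASE, 600.0, t).conc, t)
        assert val == pytest.approx(brute, rel=1e-3)

    def test_linear_limit(self):
        """For Km >> C the kinetics are linear: AUC = dose*Km/Vmax."""
        p = StructuralParams(Tlag=0.34, Tk0=0.46, V=36.2, Vmax=191.0, Km=1e6)
        assert auc(p, 600.0) == pytest.approx(600.0 * 1e6 / 191.0, rel=1e-4)

    def test_divergence_without_elimination(self):
        p = StructuralParams(Tlag=0.34, Tk0=0.46, V=36.2, Vmax=0.0, Km=20.4)
        with pytest.raises(AUCDivergenceError):
            auc(p, 600.0, t_end=np.inf)

    def test_superlinear_in_dose(self):
        """Saturable elimination: doubling the dose more than doubles AUC."""
        assert auc(BASE, 1200.0) > 2.0 * auc(BASE, 600.0)
        # Cmax nondecreasing in dose as well
        c1 = predict_conc_fast(BASE, 600.0, GRID).conc.max()
        c2 = predict_conc_fast(BASE, 1200.0, GRID).conc.max()
        assert c2 >= c1


class TestVariants:
    def test_variant_labels_and_flags(self):
        v = StructuralVariant("first", False, "linear")
        assert v.flags == (0, 0, 0)
        assert "first" in v.label()
        with pytest.raises(ValueError):
            StructuralVariant("zeroth", True, "mm")

    def test_general_kernel_agrees_with_fast_path(self):
        """The generic RK4 path reproduces the semi-analytic zero-order+MM route."""
        from rifpk import _kernels as K
        out = np.empty(GRID.shape[0])
        K._conc_general(GRID, GRID.shape[0], BASE.Tlag, BASE.Tk0, BASE.V,
                        BASE.Vmax, BASE.Km, 600.0, 1, 1, 1, out)
        ref = predict_conc_fast(BASE, 600.0, GRID).conc
        np.testing.assert_allclose(out, ref, rtol=2e-5, atol=1e-8)

    def test_first_order_conserves_mass_in_linear_case(self):
        """First-order absorption + linear elimination vs closed form (Bateman)."""
        from rifpk import _kernels as K
        ka, v, cl = 2.0, 36.2, 10.0
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
        out = np.empty(t.shape[0])
        K._conc_general(t, t.shape[0], 0.0, ka, v, cl, 1.0, 600.0, 0, 0, 0,
                        out)
        ke = cl / v
        bateman = 600.0 / v * ka / (ka - ke) * (np.exp(-ke * t)
                                                - np.exp(-ka * t))
        np.testing.assert_allclose(out, bateman, rtol=1e-5)
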