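import numpy as np
import pytest
from scipy.linalg import expm

from ocmm.core import (
    KineticParams,
    SecretionParams,
    basal_secretion,
    responsivity_indices,
    simulate_ocmm,
    simulate_secretion_driven,
)
from ocmm.glucose import CallableGlucoseSignal

KIN = KineticParams(k01=0.06, k12=0.05, k21=0.055)


def constant_glucose(gb=5.0, t_last=300.0):
    return CallableGlucoseSignal(
        g=lambda t: np.full_like(np.asarray(t, float), gb),
        dg=lambda t: np.zeros_like(np.asarray(t, float)),
        basal=gb,
        maximum=gb,
        t_last=t_last,
    )


def kinetic_matrix(kin):
    return np.array([[-(kin.k01 + kin.k21), kin.k12], [kin.k21, -kin.k12]])


def piecewise_constant_oracle(kin, knots, rates, t):
    """Closed-form CP1 under piecewise-constant secretion via matrix exponentials."""
    a = kinetic_matrix(kin)
    b = np.array([1.0, 0.0])
    x = np.zeros(2)
    out = {0.0: 0.0}
    for (t0, t1), s in zip(zip(knots[:-1], knots[1:]), rates):
        for tq in t[(t > t0) & (t <= t1)]:
            e = expm(a * (tq - t0))
            xq = e @ x + np.linalg.solve(a, (e - np.eye(2))) @ (b * s)
            out[tq] = xq[0]
        e = expm(a * (t1 - t0))
        x = e @ x + np.linalg.solve(a, (e - np.eye(2))) @ (b * s)
    return np.array([out[tq] for tq in t])


class TestKineticsOnly:
    def test_matrix_exponential_oracle_piecewise_constant(self):
        """RK45 solution matches the closed-form linear-ODE solution to 1e-6."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            kin = KineticParams(*np.exp(rng.uniform(np.log(0.02), np.log(0.15), 3)))
            knots = np.sort(np.concatenate([[0.0, 120.0], rng.uniform(5, 115, 3)]))
            rates = rng.uniform(0.0, 120.0, knots.size - 1)

            def sr(t, knots=knots, rates=rates):
                i = np.searchsorted(knots, t, side="right") - 1
                return rates[min(max(i, 0), rates.size - 1)]

            t_eval = np.linspace(0.0, 120.0, 25)
            got = simulate_secretion_driven(kin, sr, t_eval, breakpoints=knots[1:-1])
            want = piecewise_constant_oracle(kin, knots, rates, t_eval)
            scale = np.max(np.abs(want))
            np.testing.assert_allclose(got[1:], want[1:], rtol=1e-6, atol=1e-6 * scale)

    def test_superposition(self):
        """Linearity: the response to a sum of secretions is the sum of responses."""
        t = np.linspace(0, 180, 19)
        sr_a = lambda tt: 40.0 * np.exp(-tt / 60.0)
        sr_b = lambda tt: 25.0 * (1 - np.exp(-tt / 30.0))
        ya = simulate_secretion_driven(KIN, sr_a, t)
        yb = simulate_secretion_driven(KIN, sr_b, t)
        yab = simulate_secretion_driven(KIN, lambda tt: sr_a(tt) + sr_b(tt), t)
        np.testing.assert_allclose(yab, ya + yb, rtol=1e-8, atol=1e-8)

    def test_steady_state_constant_secretion(self):
        """Constant secretion s drives CP1 toward s/k01."""
        s = 30.0
        t = np.array([0.0, 2000.0])
        cp1 = simulate_secretion_driven(KIN, lambda tt: s, t)
        assert cp1[-1] == pytest.approx(s / KIN.k01, rel=1e-6)


class TestSimulateOCMM:
    def test_constant_glucose_yields_basal_output(self):
        """G == G_b (so G-h = 0 and dG/dt = 0) produces no above-basal secretion."""
        g = constant_glucose()
        sec = SecretionParams(k_d=900.0, alpha=0.05, beta=20.0, h=5.0)
        t = np.linspace(0, 300, 31)
        for method in ("rk45", "lti"):
            out = simulate_ocmm(KIN, sec, g, t, cp_basal=350.0, method=method)
            np.testing.assert_allclose(out, 350.0, atol=1e-9)

    def test_zero_secretion_parameters(self, phh_signal):
        """k_d = 0 and beta = 0 silence secretion for any glucose input."""
        sec = SecretionParams(k_d=0.0, alpha=0.05, beta=0.0, h=phh_signal.basal)
        t = np.linspace(0, 300, 31)
        out = simulate_ocmm(KIN, sec, phh_signal, t, cp_basal=420.0)
        np.testing.assert_allclose(out, 420.0, atol=1e-8)

    def test_lti_matches_rk45_on_smooth_input(self, phh_signal):
        sec = SecretionParams(k_d=3750.0, alpha=0.03, beta=16.0, h=phh_signal.basal)
        t = np.arange(0.0, 301.0, 15.0)
        a = simulate_ocmm(KIN, sec, phh_signal, t, 340.0, method="rk45")
        b = simulate_ocmm(KIN, sec, phh_signal, t, 340.0, method="lti")
        np.testing.assert_allclose(a, b, rtol=2e-3)

    def test_invalid_inputs_rejected(self, phh_signal):
        sec = SecretionParams(k_d=100.0, alpha=0.05, beta=10.0, h=5.0)
        with pytest.raises(ValueError):
            KineticParams(k01=-0.06, k12=0.05, k21=0.05)
        with pytest.raises(ValueError):
            KineticParams(k01=np.nan, k12=0.05, k21=0.05)
        with pytest.raises(ValueError):
            simulate_ocmm(KIN, sec, phh_signal, np.array([10.0, 20.0]))  # no t=0
        with pytest.raises(ValueError):
            simulate_ocmm(KIN, sec, phh_signal, np.array([0.0, 60.0]), cp_basal=-5.0)


class TestBasalSecretion:
    @pytest.mark.parametrize(
        "k01,cp1b,expected", [(0.06, 500.0, 30.0), (0.0569, 700.0, 39.83)]
    )
    def test_product(self, k01, cp1b, expected):
        assert basal_secretion(k01, cp1b) == pytest.approx(expected, rel=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            basal_secretion(0.0, 500.0)


class TestResponsivityIndices:
    def test_constant_glucose_limit(self):
        """At G == G_b the average-secretion index collapses to the basal index."""
        g = constant_glucose(gb=4.8)
        sec = SecretionParams(k_d=600.0, alpha=0.05, beta=12.0, h=4.8)
        idx = responsivity_indices(KIN, sec, g, cp1_basal=380.0, t_total=300.0)
        assert idx.phi_b == pytest.approx(KIN.k01 * 380.0 / 4.8, rel=1e-12)
        assert idx.phi_tot == pytest.approx(idx.phi_b, rel=1e-10)

    def test_basal_only_reduction(self, phh_signal):
        """With phi_d = phi_s = 0: phi_tot = phi_b * T * G_b / int(G)."""
        sec = SecretionParams(k_d=0.0, alpha=0.05, beta=0.0, h=phh_signal.basal)
        idx = responsivity_indices(KIN, sec, phh_signal, cp1_basal=340.0, t_total=300.0)
        tq = np.linspace(0.0, 300.0, 30001)
        int_g = np.trapezoid(phh_signal.value(tq), tq)
        expected = idx.phi_b * 300.0 * phh_signal.basal / int_g
        assert idx.phi_tot == pytest.approx(expected, rel=1e-6)

    def test_matches_independent_trapezoid_evaluation(self, phh_signal):
        """Simpson-grid evaluation agrees with an independent trapezoid quadrature."""
        sec = SecretionParams(k_d=3750.0, alpha=0.03, beta=16.0, h=phh_signal.basal)
        idx = responsivity_indices(KIN, sec, phh_signal, cp1_basal=340.0)
        tq = np.linspace(0.0, 300.0, 60001)
        gv = phh_signal.value(tq)
        phi_b = KIN.k01 * 340.0 / phh_signal.basal
        expected = (
            sec.k_d * (phh_signal.maximum - phh_signal.basal)
            + sec.beta * np.trapezoid(gv - sec.h, tq)
            + 300.0 * phi_b * phh_signal.basal
        ) / np.trapezoid(gv, tq)
        assert idx.phi_tot == pytest.approx(expected, rel=1e-6)
        assert 5.0 < idx.phi_tot < 40.0  # representative post-bypass magnitude

    def test_grid_resolution_invariance(self, phh_signal):
        sec = SecretionParams(k_d=3750.0, alpha=0.03, beta=16.0, h=phh_signal.basal)
        a = responsivity_indices(KIN, sec, phh_signal, 340.0, quad_dt=0.25)
        b = responsivity_indices(KIN, sec, phh_signal, 340.0, quad_dt=0.05)
        assert a.phi_tot == pytest.approx(b.phi_tot, rel=1e-7)

    def test_nonpositive_glucose_rejected(self):
        g = CallableGlucoseSignal(
            g=lambda t: 5.0 - 0.03 * np.asarray(t, float),
            dg=lambda t: np.full_like(np.asarray(t, float), -0.03),
            basal=5.0,
            maximum=5.0,
            t_last=300.0,
        )
        sec = SecretionParams(k_d=0.0, alpha=0.05, beta=1.0, h=5.0)
        with pytest.raises(ValueError, match="positive"):
            responsivity_indices(KIN, sec, g, 340.0, t_total=300.0)
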