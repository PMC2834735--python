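"""Equilibrium finding, linearization, transfer functions, Bode analysis."""

import numpy as np
import pytest

from taxisim import (
    DesignedPathway,
    EquilibriumError,
    PathwayModel,
    RationalTransferFunction,
    bode_table,
    classify_filter,
    designed_equilibrium,
    find_equilibrium,
    freq_response,
    linearize_model,
    make_bandpass,
    make_lowpass,
    transfer_function,
)

GUESS = np.array([1.0, 3.0])


def linear_relax_model(omega0=1.0, gain=1.0):
    """dx/dt = -omega0 x + gain*omega0*u, y = x (first-order lag)."""
    return PathwayModel(
        deriv=lambda x, u: np.array([-omega0 * x[0] + gain * omega0 * u]),
        output=lambda x, u: float(x[0]),
        state_dim=1,
    )


class TestFindEquilibrium:
    def test_linear_system(self):
        x = find_equilibrium(linear_relax_model(), 1.0)
        assert x[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_closed_form(self, positive_pathway):
        x = find_equilibrium(positive_pathway.as_model(), 0.5, guess=GUESS)
        v, y = designed_equilibrium(0.5, positive_pathway)
        np.testing.assert_allclose(x, [v, y], atol=1e-9)

    def test_pseudo_at_zero_input_saturates(self, pseudo_pathway):
        x = find_equilibrium(pseudo_pathway.as_model(), 0.0, guess=GUESS)
        assert x[1] == pytest.approx(pseudo_pathway.Y_T, rel=1e-9)

    def test_nonconvergence_reports_residual(self):
        # dx/dt = 1 has no equilibrium
        model = PathwayModel(deriv=lambda x, u: np.array([1.0]),
                             output=lambda x, u: float(x[0]), state_dim=1)
        with pytest.raises(EquilibriumError) as exc:
            find_equilibrium(model, 0.0)
        assert exc.value.residual is not None


class TestLinearize:
    def test_linear_model_is_fixed_point(self):
        ss = linearize_model(linear_relax_model(omega0=2.0, gain=3.0), 0.5)
        assert ss.A_mat[0, 0] == pytest.approx(-2.0, abs=1e-8)
        assert ss.B_mat[0, 0] == pytest.approx(6.0, abs=1e-8)
        assert ss.C_mat[0, 0] == pytest.approx(1.0, abs=1e-8)

    def test_jacobian_matches_analytic(self, positive_pathway):
        p = positive_pathway
        u0 = 0.5
        ss = linearize_model(p.as_model(), u0, guess=GUESS)
        v, y = designed_equilibrium(u0, p)
        A_exact = np.array([
            [-p.d_v, 0.0],
            [p.k_phos * (p.Y_T - y), -(p.k_phos * v + p.k_dephos * u0)],
        ])
        B_exact = np.array([[p.c_v], [-p.k_dephos * y]])
        np.testing.assert_allclose(ss.A_mat, A_exact, atol=1e-6)
        np.testing.assert_allclose(ss.B_mat, B_exact, atol=1e-6)

    def test_residual_at_equilibrium_is_small(self, positive_pathway):
        ss = linearize_model(positive_pathway.as_model(), 0.3, guess=GUESS)
        res = np.linalg.norm(positive_pathway.as_model().deriv(ss.x_eq, 0.3))
        assert res < 1e-9


class TestTransferFunction:
    def test_scalar_lag_realization(self):
        ss = linearize_model(linear_relax_model(omega0=0.7, gain=4.0), 0.2)
        tf = transfer_function(ss)
        expected = make_lowpass(4.0, 0.7)
        w = np.logspace(-3, 2, 50)
        np.testing.assert_allclose(tf(1j * w), expected(1j * w), rtol=1e-6)

    def test_positive_pathway_matches_reconstruction(self, positive_pathway):
        """H(s) = -k_dephos y* s / ((s+d_v)(s + k_phos v* + k_dephos u*))."""
        p = positive_pathway
        u0 = 0.5
        tf = transfer_function(linearize_model(p.as_model(), u0, guess=GUESS))
        v, y = designed_equilibrium(u0, p)
        a2 = p.k_phos * v + p.k_dephos * u0
        expected = RationalTransferFunction(
            num=[-p.k_dephos * y, 0.0],
            den=np.convolve([1.0, p.d_v], [1.0, a2]))
        w = np.logspace(-4, 3, 60)
        np.testing.assert_allclose(tf(1j * w), expected(1j * w), rtol=1e-5)
        assert tf.dc_gain() == 0.0

    def test_pseudo_dc_gain_equals_equilibrium_slope(self, pseudo_pathway):
        """|H(0)| equals d y*/du — the low-frequency gain of a non-adaptive
        pathway is exactly the sensitivity of its steady state."""
        p = pseudo_pathway
        tf = transfer_function(linearize_model(p.as_model(), 0.5, guess=GUESS))
        h = 1e-5
        slope = (designed_equilibrium(0.5 + h, p)[1]
                 - designed_equilibrium(0.5 - h, p)[1]) / (2 * h)
        assert tf.dc_gain() == pytest.approx(slope, rel=1e-4)
        assert abs(tf.dc_gain()) > 0

    @pytest.mark.parametrize("u0", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("variant", ["positive", "negative", "pseudo"])
    def test_poles_are_stable(self, variant, u0):
        p = DesignedPathway(variant=variant)
        tf = transfer_function(linearize_model(p.as_model(), u0, guess=GUESS))
        assert np.all(np.real(tf.poles) < 0)

    @pytest.mark.parametrize("variant", ["positive", "negative", "pseudo"])
    def test_dc_gain_identity(self, variant):
        """H(0) = d(equilibrium output)/d(input) for every model."""
        p = DesignedPathway(variant=variant)
        tf = transfer_function(linearize_model(p.as_model(), 0.4, guess=GUESS))
        h = 1e-5
        slope = (designed_equilibrium(0.4 + h, p)[1]
                 - designed_equilibrium(0.4 - h, p)[1]) / (2 * h)
        assert tf.dc_gain() == pytest.approx(slope, rel=1e-4, abs=1e-9)


class TestFreqResponse:
    def test_bandpass_peak_magnitude(self):
        tf = make_bandpass(16.0, 0.02, 5.0)
        mag, _ = freq_response(tf, np.sqrt(0.02 * 5.0))
        assert mag == pytest.approx(20 * np.log10(16.0), abs=1e-9)

    def test_lowpass_corner(self):
        tf = make_lowpass(8.0, 0.5)
        mag, phase = freq_response(tf, 0.5)
        assert mag == pytest.approx(20 * np.log10(8.0 / np.sqrt(2)), abs=1e-9)
        assert phase == pytest.approx(-45.0, abs=1e-9)

    def test_bandpass_low_frequency_phase_is_differentiator(self):
        tf = make_bandpass(16.0, 0.02, 5.0)
        _, phase = freq_response(tf, 1e-8)
        assert phase == pytest.approx(90.0, abs=1e-3)

    def test_zero_frequency_sentinel_for_adaptive(self):
        tf = make_bandpass(16.0, 0.02, 5.0)
        mag, _ = freq_response(tf, 0.0)
        assert mag == -np.inf

    def test_bode_table_phase_unwrapped(self):
        tf = make_bandpass(16.0, 0.02, 5.0, rank=4)
        bt = bode_table(tf)
        # rank-4 phase goes +180 deg -> -180 deg continuously
        assert bt.phase_deg[0] == pytest.approx(180.0, abs=1.0)
        assert bt.phase_deg[-1] == pytest.approx(-180.0, abs=2.0)
        assert np.all(np.abs(np.diff(bt.phase_deg)) < 90.0)


class TestClassifyFilter:
    def test_designed_positive_is_band_pass(self, positive_pathway):
        tf = transfer_function(
            linearize_model(positive_pathway.as_model(), 0.5, guess=GUESS))
        assert classify_filter(tf) == "band_pass"

    def test_pseudo_is_low_pass(self, pseudo_pathway):
        tf = transfer_function(
            linearize_model(pseudo_pathway.as_model(), 0.5, guess=GUESS))
        assert classify_filter(tf) == "low_pass"

    def test_pure_gain_is_other(self):
        assert classify_filter(RationalTransferFunction([3.0], [1.0])) == "other"

    def test_constant_gain_is_other(self):
        tf = RationalTransferFunction(num=[2.0, 2.0], den=[1.0, 1.0])
        assert classify_filter(tf) == "other"

    def test_unstable_rejected(self):
        with pytest.raises(ValueError):
            classify_filter(RationalTransferFunction([1.0], [1.0, -1.0]))


class TestLinearizationFidelity:
    def test_small_perturbation_trajectories_agree(self, positive_pathway):
        """±1% occupancy perturbation: nonlinear and linearized responses
        agree within 2% of the response amplitude over 500 s."""
        from scipy.integrate import solve_ivp

        p = positive_pathway
        u0, du = 0.5, 0.005
        model = p.as_model()
        ss = linearize_model(model, u0, guess=GUESS)
        rhs_nl = lambda t, x: np.asarray(model.deriv(x, u0 + du))
        t_eval = np.linspace(0, 500, 1001)
        sol = solve_ivp(rhs_nl, (0, 500), ss.x_eq, t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        y_nl = sol.y[1] - ss.x_eq[1]
        rhs_lin = lambda t, z: ss.A_mat @ z + ss.B_mat.ravel() * du
        sol_l = solve_ivp(rhs_lin, (0, 500), np.zeros(2), t_eval=t_eval,
                          rtol=1e-10, atol=1e-12)
        y_lin = ss.C_mat.ravel() @ sol_l.y
        amp = np.max(np.abs(y_nl))
        assert amp > 0
        assert np.max(np.abs(y_nl - y_lin)) < 0.02 * amp
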