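"""Deterministic circuit construction, steady states, sensitivity, adaptation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxyreg import (
    InputSpec,
    effective_gain,
    inhibition_value,
    integrate_ode,
    make_circuit,
    sensitivity_yss,
    static_response_distribution,
    steady_state,
    yss_static,
)
from proxyreg.circuit_core import (
    InhibitionSpec,
    ParameterError,
    circuit_from_dict,
    circuit_to_dict,
)
from proxyreg.input_models import sample_static_poisson_u

rates = st.floats(0.1, 20.0)
gains = st.floats(0.0, 100.0)


class TestNormalization:
    @given(l1=rates, l2=rates, alpha=gains, motif=st.sampled_from(["fb", "iff", "combined"]))
    @settings(max_examples=60, deadline=None)
    def test_normalization_closure(self, l1, l2, alpha, motif):
        """k1 = l1, k2 + k12·x̄ = l2 and g(x̄) = 1 hold for every circuit."""
        c = make_circuit(
            motif,
            "coupled",
            input=InputSpec(a=5.0, b=1.0, u_nominal=10.0),
            l1=l1,
            l2=l2,
            alpha_fb=alpha if motif in ("fb", "combined") else 0.0,
            alpha_ff=alpha if motif in ("iff", "combined") else 0.0,
        )
        assert c.k1 == l1
        assert c.k2 + c.k12 * c.x_bar == pytest.approx(l2, abs=1e-12)
        assert inhibition_value(c.inhibition, c.x_bar) == pytest.approx(1.0, abs=1e-12)

    def test_fig1_parameter_set(self, fig1_circuit):
        c = fig1_circuit("fb", 1.0)
        ss = steady_state(c)
        assert (ss.x_bar, ss.y_bar) == (10.0, 50.0)
        assert inhibition_value(c.inhibition, 10.0) == 1.0

    def test_iff_rate_split(self, fig1_input):
        c = make_circuit("iff", "coupled", input=fig1_input, l1=5, l2=1, alpha_ff=1.0)
        assert c.k2 == pytest.approx(0.5)
        assert c.k12 * c.x_bar == pytest.approx(0.5)

    def test_iff_no_regulation_is_plain_birth_death(self, fig1_input):
        c = make_circuit("iff", "coupled", input=fig1_input, l1=5, l2=1, alpha_ff=0.0)
        assert c.k12 == 0.0 and c.k2 == 1.0

    def test_infinite_ff_gain_is_tagged_limit(self, fig1_input):
        c = make_circuit("iff", "coupled", input=fig1_input, l1=5, l2=1, alpha_ff=math.inf)
        assert c.k2 == 0.0 and c.infinite_ff_gain
        assert c.k12 * c.x_bar == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(l1=-1.0, l2=1.0),
            dict(l1=1.0, l2=0.0),
            dict(l1=1.0, l2=1.0, alpha_fb=-0.5),
        ],
    )
    def test_bad_parameters_rejected(self, fig1_input, kwargs):
        with pytest.raises(ParameterError):
            make_circuit("fb", "coupled", input=fig1_input, **kwargs)

    def test_motif_gain_exclusivity(self, fig1_input):
        with pytest.raises(ParameterError):
            make_circuit("iff", "coupled", input=fig1_input, l1=5, l2=1, alpha_fb=1.0)


class TestInhibition:
    def test_ramp_values(self):
        g = InhibitionSpec(kind="ramp", alpha=1.0, x_anchor=10.0)
        assert inhibition_value(g, 10.0) == 1.0
        assert inhibition_value(g, 20.0) == 0.0  # x0 = 2 x̄ for alpha = 1
        assert g.x_zero == 20.0

    def test_hill_anchor_and_gain(self):
        g = InhibitionSpec(kind="hill", c=10.0, n=11.0, x_anchor=10.0)
        assert inhibition_value(g, 10.0) == pytest.approx(1.0)
        assert g.gain() == pytest.approx(10.0)  # c·n/(1+c)

    @pytest.mark.parametrize("kind,alpha,n", [("ramp", 2.0, 0.0), ("hill", 0.0, 3.0)])
    def test_monotone_decreasing_nonnegative(self, kind, alpha, n):
        g = InhibitionSpec(kind=kind, alpha=alpha, c=10.0, n=n, x_anchor=10.0)
        x = np.linspace(0, 40, 400)
        v = inhibition_value(g, x)
        assert np.all(v >= 0)
        assert np.all(np.diff(v) <= 1e-12)


class TestEffectiveGain:
    def test_ramp_gain_is_its_parameter(self, fig1_circuit):
        assert effective_gain(fig1_circuit("fb", 3.0)) == 3.0

    def test_hill_low_gain_calibration(self, fig1_input):
        # n = 1.1 at c = 10 realizes unit gain
        c = make_circuit("fb", "coupled", input=fig1_input, l1=5, l2=1,
                         alpha_fb=1.0, g_kind="hill")
        assert c.inhibition.n == pytest.approx(1.1)
        assert effective_gain(c) == pytest.approx(1.0)

    def test_combined_gain_formula(self, fig1_input):
        c = make_circuit("combined", "coupled", input=fig1_input, l1=5, l2=1,
                         alpha_fb=1.0, alpha_ff=1.0)
        assert effective_gain(c) == pytest.approx(3.0)

    def test_infinite_gain(self, fig1_input):
        c = make_circuit("iff", "coupled", input=fig1_input, l1=5, l2=1, alpha_ff=math.inf)
        assert math.isinf(effective_gain(c))


class TestSteadyStateAndOde:
    @pytest.mark.parametrize("motif,alpha", [("fb", 0.0), ("fb", 10.0), ("iff", 2.0), ("combined", 1.0)])
    def test_ode_fixed_point_matches_closed_form(self, fig1_circuit, fig1_input, motif, alpha):
        c = (
            fig1_circuit(motif, alpha)
            if motif != "combined"
            else make_circuit("combined", "coupled", input=fig1_input, l1=5, l2=1,
                              alpha_fb=alpha, alpha_ff=alpha)
        )
        ss = steady_state(c)
        traj = integrate_ode(c, 10.0, np.linspace(0, 40, 101))
        assert traj[-1] == pytest.approx([ss.x_bar, ss.y_bar], rel=1e-9)

    def test_scaling_of_means(self, fig1_input):
        c1 = make_circuit("fb", "coupled", input=fig1_input, l1=5, l2=1)
        c2 = make_circuit("fb", "coupled", input=fig1_input, l1=10, l2=1)
        assert c2.x_bar == c1.x_bar / 2 and c2.y_bar == c1.y_bar

    def test_unregulated_relaxation_is_exponential(self, fig1_circuit):
        c = fig1_circuit("fb", 0.0)
        t = np.linspace(0, 2, 21)
        traj = integrate_ode(c, 10.0, t, init_state=[0.0, 0.0])
        assert traj[:, 0] == pytest.approx(10 * (1 - np.exp(-5 * t)), rel=1e-3, abs=1e-6)
        assert traj[:, 1] == pytest.approx(50 * (1 - np.exp(-t)), rel=1e-3, abs=1e-6)

    def test_high_gain_step_adaptation(self, fig1_circuit):
        # step ū -> 2ū at gain 100: y settles within 1% of the adapted value
        c = fig1_circuit("fb", 100.0)
        traj = integrate_ode(c, 20.0, np.linspace(0, 20, 201), init_state=[10.0, 50.0])
        assert traj[-1, 1] == pytest.approx(yss_static(c, 20.0), rel=1e-2)
        assert yss_static(c, 20.0) == pytest.approx(10100 / 201, rel=1e-9)


class TestSensitivity:
    def test_unregulated_sensitivity(self, fig1_circuit):
        assert sensitivity_yss(fig1_circuit("fb", 0.0)) == pytest.approx(5.0)

    def test_infinite_gain_perfect_adaptation(self, fig1_input):
        c = make_circuit("iff", "coupled", input=fig1_input, l1=5, l2=1, alpha_ff=math.inf)
        assert sensitivity_yss(c) == 0.0

    @pytest.mark.parametrize("afb", [0.0, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("aff", [0.0, 0.5, 1.0, 2.0])
    def test_combined_matches_finite_difference(self, fig1_input, afb, aff):
        """The analytic sensitivity (with the combined effective gain) agrees
        with a centered finite difference of the ODE steady state."""
        c = make_circuit("combined", "coupled", input=fig1_input, l1=5, l2=1,
                         alpha_fb=afb, alpha_ff=aff)
        h = 1e-3
        t = np.linspace(0, 60, 61)
        y_hi = integrate_ode(c, 10.0 + h, t)[-1, 1]
        y_lo = integrate_ode(c, 10.0 - h, t)[-1, 1]
        fd = (y_hi - y_lo) / (2 * h)
        assert sensitivity_yss(c) == pytest.approx(fd, rel=1e-4)

    def test_combined_worked_example(self, fig1_input):
        c = make_circuit("combined", "coupled", input=fig1_input, l1=5, l2=1,
                         alpha_fb=1.0, alpha_ff=1.0)
        assert sensitivity_yss(c) == pytest.approx(1.25)

    def test_sensitivity_is_derivative_of_static_curve(self, fig1_circuit):
        """Symbolic check: the local sensitivity formula is the u-derivative
        of the closed-form steady-state curve at the nominal input."""
        import sympy as sp

        u, ub, al, ybar = sp.symbols("u ubar alpha ybar", positive=True)
        f = 5 * u
        fbar = 5 * ub
        yss = ybar * (1 + al) * f / (fbar * (1 + al * f / fbar))
        deriv = sp.simplify(sp.diff(yss, u).subs(u, ub))
        expected = ybar / (ub * (1 + al))  # f'/f * ȳ/(1+α) with f = 5u
        assert sp.simplify(deriv - expected) == 0


class TestStaticResponse:
    def test_nominal_input_returns_nominal_output(self, fig1_circuit):
        for alpha in [0.0, 1.0, 100.0]:
            assert yss_static(fig1_circuit("fb", alpha), 10.0) == pytest.approx(50.0)

    def test_unregulated_curve_is_linear(self, fig1_circuit):
        c = fig1_circuit("fb", 0.0)
        for u in [0.0, 3.0, 10.0, 25.0]:
            assert yss_static(c, u) == pytest.approx(5 * u / 1.0)

    def test_fb_and_iff_share_the_static_curve(self, fig1_circuit):
        """Equal-gain FB and IFF adapt identically to static input changes."""
        for alpha in [0.5, 1.0, 10.0]:
            cf, ci = fig1_circuit("fb", alpha), fig1_circuit("iff", alpha)
            for u in [2.0, 10.0, 30.0]:
                assert yss_static(cf, u) == pytest.approx(yss_static(ci, u), rel=1e-12)

    def test_variance_suppression_scales_with_gain(self, fig1_circuit):
        u = sample_static_poisson_u(10.0, 40000, seed=5)
        v0 = static_response_distribution(fig1_circuit("fb", 0.0), u)["var"]
        v100 = static_response_distribution(fig1_circuit("fb", 100.0), u)["var"]
        assert v0 == pytest.approx(25 * 10.0, rel=0.05)  # linear map of Poisson
        assert v100 <= v0 / 100.0

    def test_degenerate_samples(self, fig1_circuit):
        d = static_response_distribution(fig1_circuit("fb", 1.0), np.full(10, 10.0))
        assert d["var"] == 0.0 and d["mean"] == pytest.approx(50.0)

    @pytest.mark.parametrize("alpha", [1.0, 10.0, 100.0])
    def test_hill_matches_ramp_output_spread(self, fig1_circuit, alpha):
        """Slope-matched Hill and ramp inhibitions suppress static input
        variability to the same degree: the two output distributions differ
        by well under 1% of the nominal mean at every gain (at moderate
        gain their variances agree outright; at high gain both collapse to
        a sliver around ȳ and only the sliver widths differ)."""
        u = sample_static_poisson_u(10.0, 4000, seed=9)
        vr = static_response_distribution(fig1_circuit("fb", alpha, g_kind="ramp"), u)["var"]
        vh = static_response_distribution(fig1_circuit("fb", alpha, g_kind="hill"), u)["var"]
        y_bar = 50.0
        assert abs(np.sqrt(vh) - np.sqrt(vr)) / y_bar < 0.01
        if alpha <= 1.0:
            assert vh == pytest.approx(vr, rel=0.10)


def test_config_round_trip(fig1_input):
    c = make_circuit("combined", "decoupled", input=fig1_input, l1=5, l2=1,
                     alpha_fb=2.0, alpha_ff=0.5)
    c2 = circuit_from_dict(circuit_to_dict(c))
    assert c2 == c
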