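"""Exact FB stationary moments, penalties, optimal gain, static mixtures."""

import math

import numpy as np
import pytest

from proxyreg import (
    InputSpec,
    direct_fb_stationary,
    fb_stationary_moments,
    fb_var_y_closed,
    make_circuit,
    optimal_gain_fb,
    static_mixture_variance,
)
from proxyreg.cme_oracles import build_network, fsp_stationary_moments, ssa_simulate
from proxyreg.exact_moments_fb import _effective_ramp_alpha


class TestDirectFeedback:
    def test_unregulated_is_poisson(self):
        m = direct_fb_stationary(50.0, 1.0, 0.0)
        assert m.mean_y == pytest.approx(50.0) and m.var_y == pytest.approx(50.0)

    def test_binomial_variance_formula_vs_fsp(self, const50_input):
        """var(y) = ȳ/(1+α): the stationary law of direct self-inhibition is
        binomial; checked against the FSP oracle at ȳ=50, α=4."""
        m = direct_fb_stationary(50.0, 1.0, 4.0)
        assert m.var_y == pytest.approx(10.0, rel=1e-12)
        c = make_circuit("direct_fb", input=const50_input, l1=1, l2=1, alpha_fb=4.0)
        fsp, _ = fsp_stationary_moments(build_network(c))
        assert m.var_y == pytest.approx(fsp.var_y, rel=1e-3)
        assert m.mean_y == pytest.approx(fsp.mean_y, rel=1e-3)

    def test_high_gain_suppresses_fluctuations(self):
        vars_ = [direct_fb_stationary(50.0, 1.0, a).var_y for a in [0, 1, 10, 1000]]
        assert all(np.diff(vars_) < 0)
        assert vars_[-1] < 0.1


class TestRampMomentDerivation:
    @pytest.mark.parametrize("coupling", ["coupled", "decoupled"])
    @pytest.mark.parametrize("alpha", [0.1, 1.0, 10.0, 100.0])
    @pytest.mark.parametrize("r", [0.1, 1.0, 10.0])
    def test_moment_solution_reproduces_closed_forms(self, unit_circuit, coupling, alpha, r):
        """The linear moment-equation solution equals the closed-form
        variance decomposition var(y) = ȳ/(1+α) + P_proxy (+ P_decouple)."""
        c = unit_circuit("fb", alpha, coupling=coupling, l1=1.0 / r)
        m, pen, aeff = fb_stationary_moments(c, integer_x0=False)
        assert aeff == alpha
        assert m.var_y == pytest.approx(fb_var_y_closed(alpha, r, 50.0, coupling), rel=1e-9)
        assert pen.p_proxy == pytest.approx(
            50.0 * alpha * (alpha + r) / ((1 + alpha) * (1 + alpha + r)), rel=1e-9
        )
        if coupling == "decoupled":
            assert pen.p_decouple == pytest.approx(50.0 * alpha / (1 + alpha + r), rel=1e-9)
        assert m.mean_x == pytest.approx(c.x_bar, rel=1e-9)
        assert m.mean_y == pytest.approx(50.0, rel=1e-9)

    def test_zero_gain_penalties_vanish(self, unit_circuit):
        m, pen, _ = fb_stationary_moments(unit_circuit("fb", 0.0))
        assert m.var_y == pytest.approx(50.0)
        assert pen.p_proxy == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("coupling", ["coupled", "decoupled"])
    @pytest.mark.parametrize("alpha", [1.0, 5.0, 10.0])
    def test_exact_variance_matches_fsp(self, unit_circuit, coupling, alpha):
        """Cross-oracle agreement at (x̄, ȳ) = (50, 50)."""
        c = unit_circuit("fb", alpha, coupling=coupling)
        m, _, aeff = fb_stationary_moments(c)
        fsp, res = fsp_stationary_moments(build_network(c))
        assert res.epsilon < 1e-8
        assert m.var_y == pytest.approx(fsp.var_y, rel=1e-3)
        assert m.cov_xy == pytest.approx(fsp.cov_xy, rel=1e-3, abs=1e-3)

    def test_integer_cutoff_snapping(self):
        # x̄ = 50: alpha = 0.3 has x0 = 216.67, snapped to 217 -> alpha_eff
        assert _effective_ramp_alpha(50.0, 0.3) == pytest.approx(50.0 / 167.0)
        assert _effective_ramp_alpha(50.0, 1.0) == 1.0  # x0 = 100 already integer

    def test_penalty_monotonicity(self, unit_circuit):
        """P_proxy and P_decouple grow with gain; decoupling always costs;
        the penalty shrinks as the proxy becomes more abundant (larger r)."""
        alphas = [0.1, 0.5, 1, 2, 5, 20, 100]
        pp = [fb_var_y_closed(a, 1.0) - 1 / (1 + a) for a in alphas]
        assert all(np.diff(pp) > 0)
        pdec = [fb_var_y_closed(a, 1.0, coupling="decoupled") - fb_var_y_closed(a, 1.0)
                for a in alphas]
        assert all(np.diff(pdec) > 0)
        for a in alphas:
            assert fb_var_y_closed(a, 1.0, coupling="decoupled") > fb_var_y_closed(a, 1.0)
            assert fb_var_y_closed(a, 10.0) > fb_var_y_closed(a, 10.0) - 1e-12
        # decoupling penalty decreases in r
        for a in [1.0, 10.0]:
            p = [50 * a / (1 + a + r) for r in [0.1, 1, 10]]
            assert all(np.diff(p) < 0)

    def test_high_gain_wastes_regulation(self):
        """As α→∞ the coupled variance returns to the uncontrolled value ȳ."""
        assert fb_var_y_closed(1e6, 1.0, 50.0) == pytest.approx(50.0, rel=1e-4)


class TestOptimalGain:
    def test_small_proxy_limit(self):
        a, v, red = optimal_gain_fb(1e-6)
        assert red * 100 == pytest.approx(25.0, abs=0.1)
        assert a == pytest.approx(1.0, abs=0.01)

    def test_equal_means(self):
        a, v, red = optimal_gain_fb(1.0)
        assert round(red * 100) == 17
        assert a == pytest.approx(math.sqrt(2), abs=1e-3)

    def test_abundant_proxy_limit(self):
        _, _, red = optimal_gain_fb(1e6)
        assert red * 100 == pytest.approx(0.0, abs=0.01)

    def test_decoupled_best_without_feedback(self):
        a, v, red = optimal_gain_fb(1.0, "decoupled")
        assert a == 0.0 and red == 0.0


@pytest.fixture(scope="module")
def circuit():
    return make_circuit(
        "fb", "coupled", input=InputSpec(a=5.0, b=0.0, u_nominal=10.0),
        l1=5.0, l2=1.0, alpha_fb=0.0,
    )


class TestStaticMixture:

    def test_closed_forms(self, circuit):
        assert static_mixture_variance(circuit, "no_fb")["var_y"] == pytest.approx(300.0)
        assert static_mixture_variance(circuit, "coupled_strong")["var_y"] == pytest.approx(49.0)
        assert static_mixture_variance(circuit, "decoupled_strong")["var_y"] == pytest.approx(99.0)

    def test_finite_mixture_recovers_no_fb_at_zero_gain(self, circuit):
        res = static_mixture_variance(circuit, "finite")
        assert res["var_y"] == pytest.approx(300.0, rel=1e-6)
        assert res["E_var"] == pytest.approx(50.0, rel=1e-6)
        assert res["var_E"] == pytest.approx(250.0, rel=1e-6)

    def test_coupled_strong_always_beats_no_fb(self):
        for (a, b, l2, u) in [(5, 0, 1, 10), (2, 3, 0.5, 4), (10, 1, 2, 30)]:
            c = make_circuit("fb", "coupled", input=InputSpec(a=a, b=b, u_nominal=u),
                             l1=1.0, l2=l2)
            no = static_mixture_variance(c, "no_fb")["var_y"]
            strong = static_mixture_variance(c, "coupled_strong")["var_y"]
            assert strong < no

    def test_preference_threshold_crossing(self):
        """Strong decoupled feedback beats no feedback exactly when the input
        is noisy enough (ū below the crossing point of the closed forms)."""
        C = 50.0
        u_star = static_mixture_variance(
            make_circuit("fb", "coupled", input=InputSpec(a=5.0, b=0.0, u_nominal=10.0),
                         l1=5.0, l2=1.0),
            "no_fb",
        )["u_star"]
        for u_mean, expect_dec_better in [(0.5 * u_star, True), (2.0 * u_star, False)]:
            # hold the mean inflow C = a·ū fixed while varying the input noise
            c = make_circuit("fb", "coupled",
                             input=InputSpec(a=C / u_mean, b=0.0, u_nominal=u_mean),
                             l1=5.0, l2=1.0)
            no = static_mixture_variance(c, "no_fb")["var_y"]
            dec = static_mixture_variance(c, "decoupled_strong")["var_y"]
            assert (dec < no) == expect_dec_better

    def test_strong_coupled_mixture_matches_idealized_form(self):
        """The exact strong-gain mixture sits within a molecule of the
        idealized α→∞ value (C+b)/l2 − 1."""
        c = make_circuit("fb", "coupled", input=InputSpec(a=5.0, b=0.0, u_nominal=10.0),
                         l1=1.0, l2=1.0, alpha_fb=1e9)
        res = static_mixture_variance(c, "finite")
        assert res["var_y"] == pytest.approx(49.0, abs=1.0)

    def test_ssa_validates_no_fb_closed_form(self, circuit):
        """40k-run-scale claim at desk scale: SSA with a static Poisson input
        reproduces the law-of-total-variance closed form within 3 SE."""
        s = ssa_simulate(build_network(circuit), t_final=10.0, n_runs=4000, seed=101,
                         input_regime="static_poisson")
        assert abs(s.moments.var_y - 300.0) < 3 * s.se_var_y

    def test_ssa_validates_strong_coupled(self):
        c = make_circuit("fb", "coupled", input=InputSpec(a=5.0, b=0.0, u_nominal=10.0),
                         l1=5.0, l2=1.0, alpha_fb=1e4)
        s = ssa_simulate(build_network(c), t_final=10.0, n_runs=4000, seed=102,
                         input_regime="static_poisson")
        exact = static_mixture_variance(c, "finite")["var_y"]
        assert abs(s.moments.var_y - exact) < 3 * s.se_var_y
        assert s.moments.var_y < 60.0  # far below the unregulated 300

    def test_parameter_validation(self, circuit):
        with pytest.raises(Exception):
            static_mixture_variance(
                make_circuit("fb", "coupled", input=InputSpec(a=0.0, b=50.0, u_nominal=1.0),
                             l1=1.0, l2=1.0),
                "no_fb",
            )


class TestHillRobustness:
    def test_hill_fsp_tracks_ramp_optimum(self, const50_input):
        """FSP with slope-matched Hill inhibition (c=10, h=0..10) follows the
        exact ramp variance curve and places the optimum at the same grid
        location."""
        hs = np.arange(0, 11)
        alphas = 10.0 * hs / 11.0
        ramp_curve, hill_curve = [], []
        for a in alphas:
            ramp_curve.append(fb_var_y_closed(_eff(a), 1.0, 50.0))
            c = make_circuit("fb", "coupled", input=const50_input, l1=1.0, l2=1.0,
                             alpha_fb=a, g_kind="hill" if a > 0 else "ramp")
            m, _ = fsp_stationary_moments(build_network(c))
            hill_curve.append(m.var_y)
        i_ramp, i_hill = int(np.argmin(ramp_curve)), int(np.argmin(hill_curve))
        assert abs(i_ramp - i_hill) <= 1
        assert np.corrcoef(ramp_curve, hill_curve)[0, 1] > 0.9


def _eff(alpha):
    return _effective_ramp_alpha(50.0, alpha)
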