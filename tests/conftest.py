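import numpy as np
import pytest

from proxyreg import InputSpec, make_circuit


@pytest.fixture(scope="session")
def fig1_input():
    """Input law of the dynamic-regime examples: f(u) = 5u at ū = 10."""
    return InputSpec(a=5.0, b=0.0, u_nominal=10.0)


@pytest.fixture(scope="session")
def const50_input():
    """Constant production f = 50 (intrinsic-noise examples, x̄ = ȳ = 50 at unit rates)."""
    return InputSpec(a=0.0, b=50.0, u_nominal=1.0)


@pytest.fixture(scope="session")
def fig1_circuit(fig1_input):
    """factory: normalized Fig-1-style circuit (l1 = 5, l2 = 1)."""

    def _make(motif, alpha, coupling="coupled", g_kind="ramp"):
        return make_circuit(
            motif,
            coupling,
            input=fig1_input,
            l1=5.0,
            l2=1.0,
            alpha_fb=alpha if motif in ("fb", "direct_fb") else 0.0,
            alpha_ff=alpha if motif == "iff" else 0.0,
            g_kind=g_kind,
        )

    return _make


@pytest.fixture(scope="session")
def unit_circuit(const50_input):
    """factory: x̄ = ȳ = 50 circuit at unit degradation rates."""

    def _make(motif, alpha, coupling="coupled", g_kind="ramp", l1=1.0):
        return make_circuit(
            motif,
            coupling,
            input=const50_input,
            l1=l1,
            l2=1.0,
            alpha_fb=alpha if motif in ("fb", "direct_fb") else 0.0,
            alpha_ff=alpha if motif == "iff" else 0.0,
            g_kind=g_kind,
        )

    return _make
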