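"""Normalized proxy-regulation circuits and their deterministic analysis.

Two species are modelled: a species of interest Y and an intermediary
("proxy") X whose production is co-regulated with Y by a common input u.
Four motifs are supported:

* ``fb`` — X inhibits the production of both X and Y (negative feedback
  through a proxy),
* ``iff`` — the input up-regulates X and Y while X mediates the
  degradation of Y (incoherent feedforward),
* ``combined`` — X both inhibits production and mediates degradation of Y,
* ``direct_fb`` — a single species Y inhibiting its own production.

All circuits are normalized so that, at the nominal input ū, production
rates and the steady-state means x̄ = f(ū)/l1 and ȳ = f(ū)/l2 coincide
across motifs (k1 = l1, k2 + k12·x̄ = l2, g(x̄) = 1).  This makes circuits
with equal effective gain directly comparable: they spend the same
production/degradation fluxes on the same mean abundances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "InputSpec",
    "InhibitionSpec",
    "CircuitSpec",
    "SteadyState",
    "make_circuit",
    "inhibition_value",
    "inhibition_slope",
    "effective_gain",
    "steady_state",
    "integrate_ode",
    "sensitivity_yss",
    "yss_static",
    "static_response_distribution",
    "circuit_to_dict",
    "circuit_from_dict",
    "HILL_C_DEFAULT",
    "ALPHA_FB_INF",
]

Motif = Literal["fb", "iff", "combined", "direct_fb"]
Coupling = Literal["coupled", "decoupled"]

#: Hill strength used when calibrating the Hill inhibition to a target gain.
HILL_C_DEFAULT = 10.0

#: Finite stand-in for an "infinite" feedback gain.  The ramp inhibition
#: cannot represent a true infinite slope with finite rates, so requests for
#: alpha_fb = inf are mapped to this value with a warning.
ALPHA_FB_INF = 1e6


class ParameterError(ValueError):
    """Raised for inadmissible circuit parameters."""


@dataclass(frozen=True)
class InputSpec:
    """Production-rate input law f(u) with nominal operating point ū.

    Only the affine form f(u) = a·u + b is first-class (every printed
    result uses it); an arbitrary monotone-increasing ``func`` may be
    supplied instead, in which case derivatives are taken numerically.
    """

    a: float = 0.0
    b: float = 0.0
    u_nominal: float = 1.0
    func: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.func is None:
            if self.a < 0:
                raise ParameterError("input slope a must be >= 0")
            if self.f(self.u_nominal) <= 0:
                raise ParameterError("f(u_nominal) must be > 0")
        if self.u_nominal < 0:
            raise ParameterError("u_nominal must be >= 0")

    def f(self, u):
        if self.func is not None:
            return self.func(u)
        return self.a * u + self.b

    def f_prime(self, u: float) -> float:
        if self.func is None:
            return self.a
        h = 1e-6 * max(1.0, abs(u))
        return (self.f(u + h) - self.f(u - h)) / (2 * h)

    @property
    def f_nominal(self) -> float:
        return float(self.f(self.u_nominal))


@dataclass(frozen=True)
class InhibitionSpec:
    """Inhibition function g(x), normalized so that g(x_anchor) = 1.

    ``ramp``: g(x) = max(1 + alpha - alpha·x/x̄, 0) — linear down to zero at
    x0 = ((1+alpha)/alpha)·x̄, identically zero beyond.  Its slope at the
    anchor *is* the effective gain, and it keeps the master-equation moment
    hierarchy closed (the propensity is affine on the reachable states).

    ``hill``: g(x) = (1+c)/(1 + c·(x/x̄)^n) with strength c and exponent n;
    the slope at the anchor gives an effective gain alpha = c·n/(1+c).
    """

    kind: Literal["none", "ramp", "hill"] = "none"
    alpha: float = 0.0
    c: float = HILL_C_DEFAULT
    n: float = 0.0
    x_anchor: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.c <= 0 or self.n < 0:
            raise ParameterError("inhibition parameters must be nonnegative (c > 0)")
        if self.x_anchor <= 0:
            raise ParameterError("x_anchor must be > 0")

    @property
    def x_zero(self) -> float:
        """Ramp cutoff x0 where g reaches 0 (inf for non-ramp kinds)."""
        if self.kind == "ramp" and self.alpha > 0:
            return (1.0 + self.alpha) / self.alpha * self.x_anchor
        return math.inf

    def gain(self) -> float:
        """Effective gain -x̄·g'(x̄) at the anchor."""
        if self.kind == "none":
            return 0.0
        if self.kind == "ramp":
            return self.alpha
        return self.c * self.n / (1.0 + self.c)


def inhibition_value(g: InhibitionSpec, x):
    """Evaluate g(x) (vectorized over x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("x must be >= 0")
    if g.kind == "none":
        out = np.ones_like(x)
    elif g.kind == "ramp":
        out = np.maximum(1.0 + g.alpha - g.alpha * x / g.x_anchor, 0.0)
    else:
        out = (1.0 + g.c) / (1.0 + g.c * (x / g.x_anchor) ** g.n)
    return out if out.ndim else float(out)


def inhibition_slope(g: InhibitionSpec, x: float) -> float:
    """dg/dx at x (one-sided zero beyond the ramp cutoff)."""
    if g.kind == "none":
        return 0.0
    if g.kind == "ramp":
        return -g.alpha / g.x_anchor if x < g.x_zero else 0.0
    r = (x / g.x_anchor) ** g.n
    return -(1.0 + g.c) * g.c * g.n * r / (x * (1.0 + g.c * r) ** 2)


@dataclass(frozen=True)
class CircuitSpec:
    """A fully normalized circuit (see module docstring for the motifs)."""

    motif: Motif
    coupling: Coupling
    input: InputSpec
    l1: float
    l2: float
    alpha_fb: float
    alpha_ff: float
    k1: float
    k2: float
    k12: float
    inhibition: InhibitionSpec
    infinite_ff_gain: bool = False

    @property
    def x_bar(self) -> float:
        return self.input.f_nominal / self.l1

    @property
    def y_bar(self) -> float:
        return self.input.f_nominal / self.l2

    @property
    def n_species(self) -> int:
        return 1 if self.motif == "direct_fb" else 2


@dataclass(frozen=True)
class SteadyState:
    x_bar: float
    y_bar: float


def make_circuit(
    motif: Motif,
    coupling: Coupling = "coupled",
    input: InputSpec | None = None,
    l1: float = 1.0,
    l2: float = 1.0,
    alpha_fb: float = 0.0,
    alpha_ff: float = 0.0,
    g_kind: Literal["none", "ramp", "hill"] = "ramp",
    hill_c: float = HILL_C_DEFAULT,
) -> CircuitSpec:
    """Construct a normalized circuit.

    The derived rates satisfy the normalization conditions
    k1 = l1, k2 + k12·x̄ = l2, g(x̄) = 1, with
    k2 = l2/(1+alpha_ff) and k12·x̄ = l2·alpha_ff/(1+alpha_ff).
    ``alpha_ff = inf`` is the tagged perfect-adaptation limit k2 = 0.
    """
    if input is None:
        raise ParameterError("an InputSpec is required")
    if l1 <= 0 or l2 <= 0:
        raise ParameterError("degradation rates l1, l2 must be > 0")
    if alpha_fb < 0 or (alpha_ff < 0 and not math.isinf(alpha_ff)):
        raise ParameterError("gains must be >= 0")
    if motif == "iff" and alpha_fb != 0:
        raise ParameterError("iff circuits have no feedback gain")
    if motif in ("fb", "direct_fb") and alpha_ff != 0:
        raise ParameterError("fb circuits have no feedforward gain")

    if math.isinf(alpha_fb):
        warnings.warn(
            "alpha_fb = inf represented by the finite stand-in %g" % ALPHA_FB_INF,
            stacklevel=2,
        )
        alpha_fb = ALPHA_FB_INF

    f_bar = input.f_nominal
    x_bar = f_bar / l1
    y_bar = f_bar / l2
    anchor = y_bar if motif == "direct_fb" else x_bar

    infinite_ff = math.isinf(alpha_ff)
    if infinite_ff:
        k2 = 0.0
        k12 = l2 / x_bar
    else:
        k2 = l2 / (1.0 + alpha_ff)
        k12 = l2 * alpha_ff / (1.0 + alpha_ff) / x_bar
    if motif in ("fb", "direct_fb"):
        k2, k12 = l2, 0.0

    if motif == "iff" or alpha_fb == 0 or g_kind == "none":
        g = InhibitionSpec(kind="none", x_anchor=anchor)
    elif g_kind == "ramp":
        g = InhibitionSpec(kind="ramp", alpha=alpha_fb, x_anchor=anchor)
    else:
        # calibrate the Hill exponent so the slope at the anchor matches the
        # requested gain: alpha = c n/(1+c)  =>  n = alpha (1+c)/c
        n = alpha_fb * (1.0 + hill_c) / hill_c
        g = InhibitionSpec(kind="hill", alpha=alpha_fb, c=hill_c, n=n, x_anchor=anchor)

    return CircuitSpec(
        motif=motif,
        coupling=coupling,
        input=input,
        l1=l1,
        l2=l2,
        alpha_fb=float(alpha_fb),
        alpha_ff=float(alpha_ff) if not infinite_ff else math.inf,
        k1=l1,
        k2=k2,
        k12=k12,
        inhibition=g,
        infinite_ff_gain=infinite_ff,
    )


def effective_gain(circuit: CircuitSpec) -> float:
    """Effective regulation strength alpha of the circuit.

    fb / direct_fb: -x̄·g'(x̄); iff: x̄·k12/k2 (inf at k2 = 0);
    combined: alpha_fb + alpha_ff + alpha_fb·alpha_ff.
    """
    if circuit.motif in ("fb", "direct_fb"):
        return circuit.inhibition.gain()
    if circuit.motif == "iff":
        if circuit.k2 == 0.0:
            return math.inf
        return circuit.x_bar * circuit.k12 / circuit.k2
    a, b = circuit.inhibition.gain(), circuit.alpha_ff
    if math.isinf(b):
        return math.inf
    return a + b + a * b


def steady_state(circuit: CircuitSpec) -> SteadyState:
    """Nominal deterministic steady state (x̄, ȳ) = (f(ū)/l1, f(ū)/l2)."""
    return SteadyState(circuit.x_bar, circuit.y_bar)


def _drift(circuit: CircuitSpec, state: np.ndarray, u: float) -> np.ndarray:
    """Deterministic rate-equation right-hand side."""
    f = circuit.input.f(u)
    if circuit.motif == "direct_fb":
        y = state[0]
        prod = f * inhibition_value(circuit.inhibition, max(y, 0.0))
        return np.array([prod - circuit.l2 * y])
    x, y = state
    g = inhibition_value(circuit.inhibition, max(x, 0.0))
    prod = f * g
    dx = prod - circuit.l1 * x
    if circuit.motif == "fb":
        dy = prod - circuit.l2 * y
    else:  # iff or combined
        dy = prod - circuit.k2 * y - circuit.k12 * x * y
    return np.array([dx, dy])


class IntegrationError(RuntimeError):
    pass


def integrate_ode(
    circuit: CircuitSpec,
    u_traj,
    t_grid: Sequence[float],
    init_state: Sequence[float] | None = None,
) -> np.ndarray:
    """Integrate the rate equations along ``t_grid``.

    ``u_traj`` may be a constant, a callable t -> u, or an
    :class:`~proxyreg.input_models.InputTrajectory` (piecewise-constant).
    Fixed-step classic Runge–Kutta with substeps capped well below the
    fastest relaxation time; adequate for the piecewise-smooth ramp
    right-hand side because the fixed points sit inside the linear branch.
    Returns an array of shape (len(t_grid), n_species).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ParameterError("t_grid must be strictly increasing with >= 2 points")

    if callable(u_traj):
        u_of_t = u_traj
    elif hasattr(u_traj, "times"):
        # amortized-O(1) lookup: integration time is nondecreasing
        ev_times = [float(v) for v in u_traj.times]
        ev_vals = [float(v) for v in u_traj.values]
        n_ev = len(ev_times)
        cursor = [0]

        def u_of_t(t):
            i = cursor[0]
            if t < ev_times[i]:  # restart (new integration pass)
                i = 0
            while i + 1 < n_ev and ev_times[i + 1] <= t:
                i += 1
            cursor[0] = i
            return ev_vals[i]

    else:
        u_const = float(u_traj)
        u_of_t = lambda t: u_const  # noqa: E731

    if init_state is None:
        ss = steady_state(circuit)
        init_state = [ss.y_bar] if circuit.motif == "direct_fb" else [ss.x_bar, ss.y_bar]
    state = np.asarray(init_state, dtype=float)
    if np.any(state < 0):
        raise ParameterError("init_state must be >= 0")

    rate_scale = max(
        circuit.l1 * (1.0 + circuit.inhibition.gain()),
        circuit.l2,
        circuit.k2 + circuit.k12 * 4.0 * circuit.x_bar,
    )
    # RK4 is accurate and stable at |h·lambda| ~ 0.5 for this mildly stiff
    # piecewise-smooth system; the fixed points sit inside the ramp's
    # linear branch, so no step-size control around the kink is needed.
    dt_max = 0.5 / rate_scale

    # scalar (pure-float) drift, inlined for speed in the substep loop
    g = circuit.inhibition
    f_of_u = circuit.input.f
    l1, l2, k2c, k12c = circuit.l1, circuit.l2, circuit.k2, circuit.k12
    g_alpha, g_anchor, g_c, g_n, g_kind = g.alpha, g.x_anchor, g.c, g.n, g.kind
    motif = circuit.motif

    def g_val(x: float) -> float:
        if g_kind == "none":
            return 1.0
        if g_kind == "ramp":
            v = 1.0 + g_alpha - g_alpha * x / g_anchor
            return v if v > 0.0 else 0.0
        return (1.0 + g_c) / (1.0 + g_c * (x / g_anchor) ** g_n)

    if motif == "direct_fb":

        def drift1(y: float, u: float) -> float:
            return f_of_u(u) * g_val(y if y > 0 else 0.0) - l2 * y

        y = float(state[0])
        out = np.empty((len(t_grid), 1))
        out[0, 0] = y
        for i in range(len(t_grid) - 1):
            t0, t1 = t_grid[i], t_grid[i + 1]
            nsub = max(1, int(math.ceil((t1 - t0) / dt_max)))
            h = (t1 - t0) / nsub
            t = t0
            for _ in range(nsub):
                u0 = float(u_of_t(t))
                a = drift1(y, u0)
                b = drift1(y + 0.5 * h * a, u0)
                c = drift1(y + 0.5 * h * b, u0)
                d = drift1(y + h * c, u0)
                y += (h / 6.0) * (a + 2 * b + 2 * c + d)
                if y < 0.0:
                    y = 0.0
                t += h
            if not math.isfinite(y):
                raise IntegrationError(f"non-finite state at t={t1:g}")
            out[i + 1, 0] = y
        return out

    is_fb = motif == "fb"

    def drift2(x: float, y: float, u: float) -> tuple[float, float]:
        prod = f_of_u(u) * g_val(x if x > 0 else 0.0)
        dx = prod - l1 * x
        if is_fb:
            return dx, prod - l2 * y
        return dx, prod - k2c * y - k12c * x * y

    x, y = float(state[0]), float(state[1])
    out = np.empty((len(t_grid), 2))
    out[0] = (x, y)
    for i in range(len(t_grid) - 1):
        t0, t1 = t_grid[i], t_grid[i + 1]
        nsub = max(1, int(math.ceil((t1 - t0) / dt_max)))
        h = (t1 - t0) / nsub
        t = t0
        for _ in range(nsub):
            # u is piecewise constant between events; evaluating it once per
            # step keeps the cost down at negligible accuracy loss
            u0 = float(u_of_t(t))
            ax, ay = drift2(x, y, u0)
            bx, by = drift2(x + 0.5 * h * ax, y + 0.5 * h * ay, u0)
            cx, cy = drift2(x + 0.5 * h * bx, y + 0.5 * h * by, u0)
            dx_, dy_ = drift2(x + h * cx, y + h * cy, u0)
            x += (h / 6.0) * (ax + 2 * bx + 2 * cx + dx_)
            y += (h / 6.0) * (ay + 2 * by + 2 * cy + dy_)
            if x < 0.0:
                x = 0.0
            if y < 0.0:
                y = 0.0
            t += h
        if not (math.isfinite(x) and math.isfinite(y)):
            raise IntegrationError(f"non-finite state at t={t1:g}")
        out[i + 1] = (x, y)
    return out


def _numeric_yss(circuit: CircuitSpec, u: float) -> float:
    """Steady state of y at fixed input u by solving the fixed-point equations."""
    from scipy.optimize import brentq

    f = circuit.input.f(u)
    if f <= 0:
        return 0.0
    g = circuit.inhibition
    # g is bounded by 1+alpha (ramp) / 1+c (hill), bounding the fixed point
    g_max = (1.0 + g.c) if g.kind == "hill" else (1.0 + g.gain())
    if circuit.motif == "direct_fb":
        lo, hi = 0.0, g_max * f / circuit.l2 + 1.0
        return brentq(
            lambda y: f * inhibition_value(g, y) - circuit.l2 * y, lo, hi, xtol=1e-12
        )
    if g.kind == "none":
        x_ss = f / circuit.l1
    else:
        hi = g_max * f / circuit.l1 + 1.0
        x_ss = brentq(
            lambda x: f * inhibition_value(g, x) - circuit.l1 * x, 0.0, hi, xtol=1e-12
        )
    if circuit.motif == "fb":
        return circuit.l1 * x_ss / circuit.l2
    return f * inhibition_value(g, x_ss) / (circuit.k2 + circuit.k12 * x_ss)


def yss_static(circuit: CircuitSpec, u: float) -> float:
    """Steady-state y at a fixed input u.

    For ramp (and no) inhibition the closed form
    ȳ·(1+α)·f(u) / (f(ū)·(1 + α·f(u)/f(ū))) applies identically to the fb,
    iff and combined motifs with α the circuit's effective gain; Hill
    inhibition falls back on the numeric fixed point.
    """
    if u < 0:
        raise ParameterError("u must be >= 0")
    if circuit.inhibition.kind == "hill":
        return _numeric_yss(circuit, u)
    alpha = effective_gain(circuit)
    f_u, f_bar = circuit.input.f(u), circuit.input.f_nominal
    y_bar = circuit.y_bar
    if math.isinf(alpha):
        return y_bar if f_u > 0 else 0.0
    return y_bar * (1.0 + alpha) * f_u / (f_bar * (1.0 + alpha * f_u / f_bar))


def sensitivity_yss(circuit: CircuitSpec) -> float:
    """Local sensitivity d y_ss/d u at the nominal input (zero at infinite gain)."""
    alpha = effective_gain(circuit)
    if math.isinf(alpha):
        return 0.0
    inp = circuit.input
    return (
        inp.f_prime(inp.u_nominal)
        / inp.f_nominal
        * circuit.y_bar
        / (1.0 + alpha)
    )


def static_response_distribution(circuit: CircuitSpec, u_samples) -> dict:
    """Map a static input sample set through the steady-state curve.

    Models cell-to-cell variability: each cell holds its own constant u and
    settles to y_ss(u).  Returns the y_ss samples plus mean/variance/cv.
    """
    u_samples = np.asarray(u_samples, dtype=float)
    if u_samples.size == 0:
        raise ParameterError("u_samples must be non-empty")
    if circuit.inhibition.kind == "hill":
        y = np.array([_numeric_yss(circuit, float(u)) for u in u_samples])
    else:
        alpha = effective_gain(circuit)
        f_u = np.asarray(circuit.input.f(u_samples), dtype=float)
        f_bar = circuit.input.f_nominal
        if math.isinf(alpha):
            y = np.where(f_u > 0, circuit.y_bar, 0.0)
        else:
            y = circuit.y_bar * (1 + alpha) * f_u / (f_bar * (1 + alpha * f_u / f_bar))
    mean = float(np.mean(y))
    var = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    return {
        "y_ss": y,
        "mean": mean,
        "var": var,
        "cv": math.sqrt(var) / mean if mean > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# config round-trip


def circuit_to_dict(circuit: CircuitSpec) -> dict:
    return {
        "motif": circuit.motif,
        "coupling": circuit.coupling,
        "f": {"a": circuit.input.a, "b": circuit.input.b},
        "u_nominal": circuit.input.u_nominal,
        "l1": circuit.l1,
        "l2": circuit.l2,
        "alpha_fb": circuit.alpha_fb,
        "alpha_ff": "inf" if circuit.infinite_ff_gain else circuit.alpha_ff,
        "g": {"kind": circuit.inhibition.kind, "c": circuit.inhibition.c},
    }


def circuit_from_dict(cfg: dict) -> CircuitSpec:
    alpha_ff = cfg.get("alpha_ff", 0.0)
    if alpha_ff in ("inf", "infinity"):
        alpha_ff = math.inf
    g = cfg.get("g", {})
    return make_circuit(
        motif=cfg["motif"],
        coupling=cfg.get("coupling", "coupled"),
        input=InputSpec(
            a=cfg["f"].get("a", 0.0),
            b=cfg["f"].get("b", 0.0),
            u_nominal=cfg["u_nominal"],
        ),
        l1=cfg["l1"],
        l2=cfg["l2"],
        alpha_fb=cfg.get("alpha_fb", 0.0),
        alpha_ff=alpha_ff,
        g_kind=g.get("kind", "ramp"),
        hill_c=g.get("c", HILL_C_DEFAULT),
    )
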