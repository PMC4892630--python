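"""Input-to-output transfer behavior of the linearized circuits.

For small input fluctuations u(t) = ū + δ(t) and y(t) near ȳ, the circuit
acts as a linear filter from δ to y.  The squared H2 norm of that filter
equals the stationary variance of y when δ is white noise, and is obtained
from the Lyapunov equation A·P + P·Aᵀ + B·Bᵀ = 0 as C·P·Cᵀ with C = [0, 1].

High-gain feedback drives this variance to zero, while any incoherent
feedforward implementation is bounded below by σ²/(2(l1+l2)): the FB
regulates the proxy's own dynamics as well as y's, the IFF does not.  The
module also provides an Euler–Maruyama ensemble simulator of the full
nonlinear ODEs with additive noise (to check the H2 predictions away from
the linearization) and the coefficient of variation of y driven by a
birth–death input trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg

from .circuit_core import (
    CircuitSpec,
    ParameterError,
    _drift,
    inhibition_slope,
    integrate_ode,
)
from .input_models import InputTrajectory

__all__ = [
    "TransferModel",
    "linearize",
    "h2_norm_squared",
    "iff_h2_floor",
    "simulate_sde_ensemble",
    "cv_dynamic_response",
]


@dataclass(frozen=True)
class TransferModel:
    A: np.ndarray  # 2x2 drift
    B: np.ndarray  # input vector (2,)
    C: np.ndarray  # output selector (2,), y component
    noise_intensity: float


def linearize(
    circuit: CircuitSpec,
    noise_mode: Literal["input_derivative", "additive"] = "additive",
    sigma: float = 1.0,
) -> TransferModel:
    """Linearize about the nominal steady state.

    ``additive``: B = σ·[1, 1]ᵀ — the same white-noise term added to both
    rate equations (the construction used for the ensemble experiments).
    ``input_derivative``: B = f'(ū)·[1, 1]ᵀ — noise entering through the
    production rate's dependence on u.
    """
    if circuit.motif == "direct_fb":
        raise ParameterError("transfer analysis applies to two-species circuits")
    x_bar, y_bar = circuit.x_bar, circuit.y_bar
    f_bar = circuit.input.f_nominal
    dprod = f_bar * inhibition_slope(circuit.inhibition, x_bar)
    A = np.array(
        [
            [dprod - circuit.l1, 0.0],
            [dprod - circuit.k12 * y_bar, -(circuit.k2 + circuit.k12 * x_bar)],
        ]
    )
    if np.any(np.real(np.linalg.eigvals(A)) >= 0):
        raise ParameterError("drift matrix is not Hurwitz")
    scale = sigma if noise_mode == "additive" else circuit.input.f_prime(circuit.input.u_nominal)
    return TransferModel(A=A, B=scale * np.ones(2), C=np.array([0.0, 1.0]), noise_intensity=sigma)


def h2_norm_squared(model: TransferModel) -> float:
    """Squared H2 norm = stationary var(y) under white-noise forcing."""
    P = linalg.solve_continuous_lyapunov(model.A, -np.outer(model.B, model.B))
    val = float(model.C @ P @ model.C)
    if not np.isfinite(val):
        raise FloatingPointError("Lyapunov solve returned non-finite covariance")
    return val


def iff_h2_floor(l1: float, l2: float, sigma: float) -> float:
    """Lower bound σ²/(2(l1+l2)) on var(y) over all IFF gains (attained as
    α_ff → ∞)."""
    return sigma * sigma / (2.0 * (l1 + l2))


def simulate_sde_ensemble(
    circuit: CircuitSpec,
    sigma: float,
    t_final: float,
    n_runs: int,
    seed: int,
    dt: float | None = None,
    n_bootstrap: int = 200,
) -> dict:
    """Ensemble variance of y(t_final) under additive white noise.

    Euler–Maruyama on the nonlinear rate equations plus σ·[1,1]ᵀ·dW (one
    shared Wiener process — correlated forcing of both equations), states
    reflected at 0 by clipping.  Returns the ensemble variance with a
    bootstrap 95% CI.
    """
    if n_runs < 100:
        raise ParameterError("n_runs >= 100 required for a meaningful ensemble")
    alpha = circuit.inhibition.gain()
    stab = 0.1 / max(circuit.l1 * (1.0 + alpha), circuit.l2, circuit.k2 + 2 * circuit.k12 * circuit.x_bar)
    if dt is None:
        dt = min(1e-3, stab)
    elif dt > 2 * stab:
        raise ParameterError(f"dt={dt} violates the stability bound {2*stab:.2e}")
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_final / dt))
    u_bar = circuit.input.u_nominal
    state = np.empty((n_runs, 2))
    state[:, 0] = circuit.x_bar
    state[:, 1] = circuit.y_bar
    sq = sigma * math.sqrt(dt)
    for _ in range(n_steps):
        # vectorized drift (same algebra as circuit_core._drift)
        f = circuit.input.f(u_bar)
        from .circuit_core import inhibition_value

        g = inhibition_value(circuit.inhibition, state[:, 0])
        prod = f * g
        dx = prod - circuit.l1 * state[:, 0]
        if circuit.motif == "fb":
            dy = prod - circuit.l2 * state[:, 1]
        else:
            dy = prod - circuit.k2 * state[:, 1] - circuit.k12 * state[:, 0] * state[:, 1]
        dw = rng.standard_normal(n_runs) * sq
        state[:, 0] = np.maximum(state[:, 0] + dx * dt + dw, 0.0)
        state[:, 1] = np.maximum(state[:, 1] + dy * dt + dw, 0.0)
    y = state[:, 1]
    var = float(np.var(y, ddof=1))
    boot = np.var(y[rng.integers(0, n_runs, size=(n_bootstrap, n_runs))], axis=1, ddof=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "var_y": var,
        "ci_lo": float(lo),
        "ci_hi": float(hi),
        "n_runs": n_runs,
        "dt": dt,
        "t_final": t_final,
    }


def cv_dynamic_response(
    circuit: CircuitSpec,
    u_traj: InputTrajectory,
    t_grid: np.ndarray,
    discard_fraction: float = 0.1,
) -> dict:
    """Coefficient of variation of y(t) along a dynamic input trajectory.

    Integrates the rate equations driven by the piecewise-constant input
    and returns std(y)/mean(y) over the grid after discarding the initial
    transient (first 10% by default).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    traj = integrate_ode(circuit, u_traj, t_grid)
    keep = t_grid >= t_grid[0] + discard_fraction * (t_grid[-1] - t_grid[0])
    y = traj[keep, -1]
    mean = float(np.mean(y))
    if mean < 1e-12:
        raise ParameterError("mean(y) ~ 0: cv undefined")
    return {
        "cv": float(np.std(y) / mean),
        "mean_y": mean,
        "std_y": float(np.std(y)),
        "discard_fraction": discard_fraction,
    }
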