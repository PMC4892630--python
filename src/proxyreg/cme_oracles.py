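"""Ground-truth solvers for the circuit master equations.

Two independent oracles validate every analytic result in the package:

* :func:`fsp_stationary_moments` — finite state projection: the stationary
  distribution of the truncated chemical master equation, obtained as the
  null vector of the truncated generator with reflecting truncation
  (outflow propensities zeroed).  The neglected-mass indicator ε is the
  stationary probability sitting on boundary layers that still want to
  flow out; bounds auto-expand until ε is below tolerance.
* :func:`ssa_simulate` — exact-jump stochastic simulation (Gillespie's
  direct method), vectorized across independent runs, with optional
  static-Poisson input (one u drawn per run — cell-to-cell variability)
  or a birth–death input co-simulated as a third species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .circuit_core import CircuitSpec, ParameterError, inhibition_value
from .exact_moments_fb import StationaryMoments

__all__ = [
    "Channel",
    "ReactionNetwork",
    "FSPResult",
    "build_network",
    "fsp_stationary_moments",
    "ssa_simulate",
    "SSAResult",
]


@dataclass(frozen=True)
class Channel:
    """One reaction channel: propensity = const · Π state_i^pow_i · gfac(x_g)."""

    stoich: tuple[int, ...]
    const: float
    powers: tuple[int, ...]
    gfac: Callable[[np.ndarray], np.ndarray] | None = None
    gfac_species: int = 0
    input_scaled: bool = False  # propensity proportional to f(u)
    label: str = ""

    def propensity(self, states: np.ndarray) -> np.ndarray:
        """Vectorized propensity over an array of states (..., n_species)."""
        w = np.full(states.shape[:-1], self.const, dtype=float)
        for i, p in enumerate(self.powers):
            if p:
                w = w * states[..., i] ** p
        if self.gfac is not None:
            w = w * self.gfac(states[..., self.gfac_species])
        return w


@dataclass(frozen=True)
class ReactionNetwork:
    """Species labels, channels, and a hard support bound per species
    (None = unbounded, truncation chosen adaptively)."""

    species: tuple[str, ...]
    channels: tuple[Channel, ...]
    hard_bounds: tuple[int | None, ...]
    circuit: CircuitSpec | None = None


def build_network(circuit: CircuitSpec) -> ReactionNetwork:
    """Reaction channels of a normalized circuit (input fixed at ū).

    Coupled production emits +1 to both species through one channel;
    decoupled production uses two channels with identical rate laws.
    Channels with zero rate constant are dropped.
    """
    f_bar = circuit.input.f_nominal
    g = circuit.inhibition

    if circuit.motif == "direct_fb":
        gf = (lambda y: inhibition_value(g, y)) if g.kind != "none" else None
        ymax = int(math.ceil(g.x_zero)) if g.kind == "ramp" else None
        chans = [
            Channel((1,), f_bar, (0,), gf, 0, True, "prod_y"),
            Channel((-1,), circuit.l2, (1,), None, 0, False, "deg_y"),
        ]
        return ReactionNetwork(("y",), tuple(chans), (ymax,), circuit)

    gf = (lambda x: inhibition_value(g, x)) if g.kind != "none" else None
    xmax = int(math.ceil(g.x_zero)) if g.kind == "ramp" else None
    chans: list[Channel] = []
    if circuit.coupling == "coupled":
        chans.append(Channel((1, 1), f_bar, (0, 0), gf, 0, True, "prod_xy"))
    else:
        chans.append(Channel((1, 0), f_bar, (0, 0), gf, 0, True, "prod_x"))
        chans.append(Channel((0, 1), f_bar, (0, 0), gf, 0, True, "prod_y"))
    chans.append(Channel((-1, 0), circuit.k1, (1, 0), None, 0, False, "deg_x"))
    if circuit.k2 > 0:
        chans.append(Channel((0, -1), circuit.k2, (0, 1), None, 0, False, "deg_y"))
    if circuit.k12 > 0:
        chans.append(Channel((0, -1), circuit.k12, (1, 1), None, 0, False, "deg_y_med"))
    return ReactionNetwork(("x", "y"), tuple(chans), (xmax, None), circuit)


@dataclass(frozen=True)
class FSPResult:
    bounds: tuple[int, ...]
    probability: np.ndarray  # shape (b0+1,) or (b0+1, b1+1)
    epsilon: float


class TruncationError(RuntimeError):
    pass


def _fsp_solve(net: ReactionNetwork, bounds: tuple[int, ...]) -> tuple[np.ndarray, float]:
    """Stationary distribution on the box [0,b0]×…, reflecting truncation."""
    shape = tuple(b + 1 for b in bounds)
    nsp = len(shape)
    # enumerate with the largest axis outermost: the sparse LU bandwidth is
    # then the smallest axis size, which keeps fill-in modest on long boxes
    perm = tuple(sorted(range(nsp), key=lambda d: -shape[d]))
    inv = tuple(int(i) for i in np.argsort(perm))
    pshape = tuple(shape[p] for p in perm)
    pbounds = np.array([bounds[p] for p in perm])
    n = int(np.prod(shape))
    pgrids = np.indices(pshape).reshape(nsp, -1).T  # permuted coords
    grids = pgrids[:, inv]  # original species order
    idx = np.arange(n)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ch in net.channels:
        w = ch.propensity(grids.astype(float))
        ptgt = pgrids + np.asarray([ch.stoich[p] for p in perm])
        # reflect per dimension: clip the target into the box, keeping the
        # within-box components of multi-species jumps alive (otherwise a
        # coupled production blocked at one boundary could strand the chain)
        ptgt = np.clip(ptgt, 0, pbounds)
        ok = (w > 0) & np.any(ptgt != pgrids, axis=1)
        tgt_idx = np.ravel_multi_index(tuple(ptgt[ok].T), pshape)
        rows.append(tgt_idx)
        cols.append(idx[ok])
        vals.append(w[ok])
        diag[idx[ok]] -= w[ok]
    A = sparse.coo_matrix(
        (np.concatenate(vals + [diag]), (np.concatenate(rows + [idx]), np.concatenate(cols + [idx]))),
        shape=(n, n),
    ).tocsr()
    # replace one balance equation by the normalization constraint
    A = A.tolil()
    A[0, :] = 1.0
    rhs = np.zeros(n)
    rhs[0] = 1.0
    pi = spsolve(A.tocsr(), rhs)
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()
    pi = np.transpose(pi.reshape(pshape), axes=inv).reshape(-1)

    # boundary mass through which some reaction would leave the box
    eps = 0.0
    pi_grid = pi.reshape(shape)
    for d, b in enumerate(bounds):
        if net.hard_bounds[d] is not None and b >= net.hard_bounds[d]:
            continue  # support genuinely ends here (e.g. ramp cutoff)
        eps += float(np.take(pi_grid, b, axis=d).sum())
    return pi_grid, eps


def _default_bounds(net: ReactionNetwork) -> list[int]:
    c = net.circuit
    out = []
    for d, sp in enumerate(net.species):
        if net.hard_bounds[d] is not None:
            out.append(net.hard_bounds[d])
            continue
        mean = c.y_bar if sp == "y" else c.x_bar
        out.append(int(math.ceil(mean + 8.0 * math.sqrt(max(mean, 1.0)) + 10)))
    return out


def fsp_stationary_moments(
    net: ReactionNetwork,
    bounds: Sequence[int] | None = None,
    eps_tol: float = 1e-8,
    max_states: int = 400_000,
) -> tuple[StationaryMoments, FSPResult]:
    """Stationary moments via finite state projection.

    Bounds auto-expand (per species without a hard support bound) until the
    boundary mass ε falls below ``eps_tol``; raises
    :class:`TruncationError` if the state-space cap is hit first.
    """
    bounds = list(bounds) if bounds is not None else _default_bounds(net)
    while True:
        if np.prod([b + 1 for b in bounds]) > max_states:
            raise TruncationError(f"bounds {bounds} exceed the state cap; ε not yet {eps_tol}")
        pi, eps = _fsp_solve(net, tuple(bounds))
        if eps <= eps_tol:
            break
        bounds = [
            b if net.hard_bounds[d] is not None else int(b * 1.4) + 5
            for d, b in enumerate(bounds)
        ]

    shape = pi.shape
    if len(shape) == 1:
        y = np.arange(shape[0])
        mean_y = float(np.sum(pi * y))
        var_y = float(np.sum(pi * y * y) - mean_y**2)
        moments = StationaryMoments(math.nan, mean_y, math.nan, var_y, math.nan, "fsp")
    else:
        xg = np.arange(shape[0])[:, None]
        yg = np.arange(shape[1])[None, :]
        mx = float(np.sum(pi * xg))
        my = float(np.sum(pi * yg))
        moments = StationaryMoments(
            mean_x=mx,
            mean_y=my,
            var_x=float(np.sum(pi * xg * xg) - mx * mx),
            var_y=float(np.sum(pi * yg * yg) - my * my),
            cov_xy=float(np.sum(pi * xg * yg) - mx * my),
            method="fsp",
        )
    return moments, FSPResult(tuple(bounds), pi, eps)


@dataclass(frozen=True)
class SSAResult:
    moments: StationaryMoments
    se_mean_y: float
    se_var_y: float
    n_runs: int
    time_avg_mean_y: float = math.nan
    time_avg_cv_y: float = math.nan


def ssa_simulate(
    net: ReactionNetwork,
    t_final: float,
    n_runs: int,
    seed: int,
    input_regime: Literal["fixed", "static_poisson", "birth_death"] = "fixed",
    birth_rate: float = 0.0,
    death_rate: float = 0.0,
    n_bootstrap: int = 200,
) -> SSAResult:
    """Exact-jump (direct-method) simulation, vectorized across runs.

    ``static_poisson`` draws one u ~ Poisson(ū) per run and scales the
    input-dependent propensities by f(u)/f(ū); ``birth_death`` co-simulates
    u as an extra birth–death species with the given rates.  Cross-run
    moments of y(t_final) are returned with bootstrap standard errors,
    together with time-averaged statistics over the second half of each run.
    """
    if n_runs < 1:
        raise ParameterError("n_runs >= 1 required")
    rng = np.random.default_rng(seed)
    circ = net.circuit
    nsp = len(net.species)
    y_idx = net.species.index("y")
    f_bar = circ.input.f_nominal

    states = np.empty((n_runs, nsp), dtype=np.int64)
    for d, sp in enumerate(net.species):
        mean = circ.y_bar if sp == "y" else circ.x_bar
        states[:, d] = int(round(mean))

    if input_regime == "fixed":
        f_scale = np.ones(n_runs)
        u = None
    elif input_regime == "static_poisson":
        u = rng.poisson(circ.input.u_nominal, size=n_runs).astype(float)
        f_scale = np.asarray(circ.input.f(u), dtype=float) / f_bar
        u = None  # static: enters only through f_scale
    elif input_regime == "birth_death":
        if birth_rate <= 0 or death_rate <= 0:
            raise ParameterError("birth_death regime needs positive rates")
        u = np.full(n_runs, int(round(birth_rate / death_rate)), dtype=np.int64)
        f_scale = None
    else:
        raise ParameterError(f"unknown input_regime {input_regime!r}")

    n_chan = len(net.channels)
    k_tot = n_chan + (2 if input_regime == "birth_death" else 0)
    stoich = np.zeros((k_tot, nsp), dtype=np.int64)
    for k, ch in enumerate(net.channels):
        stoich[k] = ch.stoich

    t = np.zeros(n_runs)
    active = np.ones(n_runs, dtype=bool)
    t_burn = 0.5 * t_final
    acc_t = np.zeros(n_runs)
    acc_y = np.zeros(n_runs)
    acc_y2 = np.zeros(n_runs)

    W = np.empty((n_runs, k_tot))
    while np.any(active):
        sf = states.astype(float)
        for k, ch in enumerate(net.channels):
            w = ch.propensity(sf)
            if ch.input_scaled:
                if f_scale is not None:
                    w = w * f_scale
                else:
                    w = w * np.asarray(circ.input.f(u.astype(float))) / f_bar
            W[:, k] = w
        if input_regime == "birth_death":
            W[:, n_chan] = birth_rate
            W[:, n_chan + 1] = death_rate * u
        W[~active] = 0.0
        a0 = W.sum(axis=1)
        stuck = active & (a0 <= 0)
        if np.any(stuck):
            t[stuck] = t_final
            active = active & ~stuck
            if not np.any(active):
                break
        dt = np.full(n_runs, np.inf)
        act = active
        dt[act] = rng.exponential(1.0, size=int(act.sum())) / a0[act]
        t_new = t + dt
        # time-average accumulation over [t_burn, t_final]
        seg_lo = np.maximum(t, t_burn)
        seg_hi = np.minimum(t_new, t_final)
        seg = np.clip(seg_hi - seg_lo, 0.0, None)
        seg = np.where(act, seg, 0.0)
        yv = states[:, y_idx].astype(float)
        acc_t += seg
        acc_y += seg * yv
        acc_y2 += seg * yv * yv

        fire = act & (t_new < t_final)
        done = act & ~fire
        t[done] = t_final
        active = active & ~done
        if np.any(fire):
            r = rng.random(n_runs) * a0
            cum = np.cumsum(W, axis=1)
            chan = (cum < r[:, None]).sum(axis=1)
            chan = np.minimum(chan, k_tot - 1)
            which = np.flatnonzero(fire)
            ck = chan[which]
            main = ck < n_chan
            states[which[main]] += stoich[ck[main]]
            if input_regime == "birth_death":
                ub = which[ck == n_chan]
                ud = which[ck == n_chan + 1]
                u[ub] += 1
                u[ud] -= 1
            t[which] = t_new[which]

    y_end = states[:, y_idx].astype(float)
    mean_y = float(y_end.mean())
    var_y = float(y_end.var(ddof=1))
    # bootstrap SEs
    boot_idx = rng.integers(0, n_runs, size=(n_bootstrap, n_runs))
    bm = y_end[boot_idx]
    se_mean = float(bm.mean(axis=1).std(ddof=1))
    se_var = float(bm.var(axis=1, ddof=1).std(ddof=1))

    tav_mean = acc_y / np.maximum(acc_t, 1e-300)
    tav_var = acc_y2 / np.maximum(acc_t, 1e-300) - tav_mean**2
    tav_cv = np.sqrt(np.maximum(tav_var, 0.0)) / np.maximum(tav_mean, 1e-300)

    mx = math.nan
    vx = math.nan
    cxy = math.nan
    if nsp == 2:
        x_end = states[:, 0].astype(float)
        mx = float(x_end.mean())
        vx = float(x_end.var(ddof=1))
        cxy = float(np.cov(x_end, y_end)[0, 1])
    moments = StationaryMoments(mx, mean_y, vx, var_y, cxy, "ssa")
    return SSAResult(
        moments=moments,
        se_mean_y=se_mean,
        se_var_y=se_var,
        n_runs=n_runs,
        time_avg_mean_y=float(tav_mean.mean()),
        time_avg_cv_y=float(np.median(tav_cv)),
    )
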