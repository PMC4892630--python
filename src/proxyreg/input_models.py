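"""Synthetic generators for the three input regimes of the noise analysis.

* static Poisson input — cell-to-cell variability: each cell draws one
  constant input level u ~ Poisson(ū) (e.g. plasmid copy number),
* birth–death input — a dynamic input u(t) following an M/M/inf birth–death
  process with birth rate b_r and death rate d (stationary law Poisson(b_r/d),
  autocorrelation time 1/d),
* white noise — an additive intensity sigma consumed by the SDE integrator
  in :mod:`proxyreg.frequency_response`; it is not pre-sampled here because
  its sample path depends on the integrator step.

All generators are bit-reproducible for a fixed seed; per-replicate
sub-streams are derived deterministically with numpy's SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "InputModel",
    "InputTrajectory",
    "sample_static_poisson_u",
    "simulate_birth_death_u",
]


@dataclass(frozen=True)
class InputModel:
    """Descriptor of one input regime (static_poisson | birth_death | white_noise)."""

    regime: Literal["static_poisson", "birth_death", "white_noise"]
    u_mean: float = 0.0
    birth_rate: float = 0.0
    death_rate: float = 0.0
    noise_intensity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.birth_rate, self.death_rate, self.noise_intensity) < 0:
            raise ValueError("rates and noise intensity must be >= 0")
        if self.regime == "birth_death" and self.death_rate > 0:
            object.__setattr__(self, "u_mean", self.birth_rate / self.death_rate)


@dataclass(frozen=True)
class InputTrajectory:
    """Right-continuous piecewise-constant trajectory: u(t) = values[i] on
    [times[i], times[i+1])."""

    times: np.ndarray
    values: np.ndarray

    def value_at(self, t):
        """u(t), vectorized; constant extrapolation beyond the last event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        return self.values[idx]

    def time_average(self, t_start: float = 0.0, t_end: float | None = None) -> float:
        """Exact time average of the step function over [t_start, t_end]."""
        if t_end is None:
            t_end = float(self.times[-1])
        knots = np.concatenate(([t_start], self.times[(self.times > t_start) & (self.times < t_end)], [t_end]))
        vals = self.value_at(knots[:-1])
        return float(np.sum(vals * np.diff(knots)) / (t_end - t_start))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t": self.times, "u": self.values}).to_csv(path, index=False)


def sample_static_poisson_u(u_mean: float, n_samples: int, seed: int) -> np.ndarray:
    """Draw n_samples constant input levels u ~ Poisson(u_mean)."""
    if u_mean <= 0:
        raise ValueError("u_mean must be > 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.poisson(u_mean, size=n_samples)


def simulate_birth_death_u(
    birth_rate: float,
    death_rate: float,
    t_final: float,
    seed: int,
    u0: int | None = None,
) -> InputTrajectory:
    """Exact event-driven simulation of the birth-death input process.

    Birth propensity b_r, death propensity d·u.  Starts at u0 (defaults to
    round(b_r/d), the stationary mean) and records every jump up to t_final.
    """
    if birth_rate <= 0 or death_rate <= 0 or t_final <= 0:
        raise ValueError("birth_rate, death_rate, t_final must be > 0")
    rng = np.random.default_rng(seed)
    u = int(round(birth_rate / death_rate)) if u0 is None else int(u0)
    # preallocate generously: expected event count plus a safety margin
    n_exp = int(2 * (birth_rate + death_rate * max(u, birth_rate / death_rate)) * t_final) + 100
    times = np.empty(n_exp)
    values = np.empty(n_exp, dtype=np.int64)
    times[0], values[0] = 0.0, u
    t, k = 0.0, 1
    while True:
        a_birth = birth_rate
        a_death = death_rate * u
        a_tot = a_birth + a_death
        t += rng.exponential(1.0 / a_tot)
        if t >= t_final:
            break
        u = u + 1 if rng.random() * a_tot < a_birth else u - 1
        if k >= len(times):
            times = np.concatenate([times, np.empty(len(times))])
            values = np.concatenate([values, np.empty(len(values), dtype=np.int64)])
        times[k], values[k] = t, u
        k += 1
    return InputTrajectory(times=times[:k].copy(), values=values[:k].copy())
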