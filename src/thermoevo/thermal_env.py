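"""Bounded stochastic temperature process.

The environment is a dimensionless temperature on (0, 1) that combines a
deterministic sinusoid with multiplicative, sigmoid-transformed Gaussian
noise:

    tau_t = (tau0 + m * sin(omega * t)) * sigmoid(sigma_eps * X_t)

with ``X_t ~ N(0, 1)`` independent across steps and
``sigmoid(z) = 1 / (1 + exp(-z))``.  Because the sigmoid maps the real line
into (0, 1), every draw stays strictly inside (0, 1) whenever the sinusoid
is bounded away from 0 and 1, i.e. ``tau0 - m > 0`` and ``tau0 + m < 1``.
With ``sigma_eps = 0`` the sigmoid is identically 1/2 and the series
reduces *exactly* to the deterministic wave ``(tau0 + m sin(omega t)) / 2``;
by the symmetry of the sigmoid under ``X -> -X`` the long-run mean with
``m = 0`` is ``tau0 / 2``.

Time is discrete, ``t = 0, 1, 2, ...``; there is no sub-step interpolation.
Noise streams are identified by an explicit integer seed so that
comparative evaluations (resident versus mutant, finite-difference
stencils) can share one frozen realization (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "ThermalRegime",
    "TemperatureSeries",
    "generate_temperature",
    "deterministic_component",
]


@dataclass(frozen=True)
class ThermalRegime:
    """Parameters of the bounded stochastic temperature process.

    Parameters
    ----------
    tau0
        Vertical shift of the sinusoid (twice the long-run mean
        temperature); dimensionless.
    m
        Sine magnitude, ``m >= 0``.
    omega
        Sine frequency in radians per time step.
    sigma_eps
        Environmental noise magnitude, ``sigma_eps >= 0``.
    seed
        Identifier of the pseudo-random noise stream (numpy PCG64).
    """

    tau0: float = 0.5
    m: float = 0.25
    omega: float = 13 * math.pi / 20
    sigma_eps: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tau0 - self.m > 0.0):
            raise ValueError(
                f"boundedness requires tau0 - m > 0, got tau0={self.tau0}, m={self.m}"
            )
        if not (self.tau0 + self.m < 1.0):
            raise ValueError(
                f"boundedness requires tau0 + m < 1, got tau0={self.tau0}, m={self.m}"
            )
        if self.m < 0.0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.sigma_eps < 0.0:
            raise ValueError(f"sigma_eps must be >= 0, got {self.sigma_eps}")


@dataclass(frozen=True)
class TemperatureSeries:
    """A realized temperature series together with its noise draws."""

    values: np.ndarray
    noise_draws: np.ndarray
    regime: ThermalRegime = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.noise_draws):
            raise ValueError("values and noise_draws must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def deterministic_component(regime: ThermalRegime, t) -> float | np.ndarray:
    """Noise-free temperature ``(tau0 + m sin(omega t)) / 2`` at step(s) *t*.

    This is the exact ``sigma_eps = 0`` limit of the stochastic process.
    """
    t = np.asarray(t, dtype=float)
    out = (regime.tau0 + regime.m * np.sin(regime.omega * t)) / 2.0
    return out if out.ndim else float(out)


def generate_temperature(regime: ThermalRegime, horizon: int) -> TemperatureSeries:
    """Draw a temperature series of length *horizon* from the regime's stream.

    The same ``(regime, horizon)`` always yields a bit-identical series.
    All values are strictly inside (0, 1).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be a positive integer, got {horizon}")
    rng = np.random.default_rng(regime.seed)
    x = rng.standard_normal(horizon)
    t = np.arange(horizon, dtype=float)
    sinusoid = regime.tau0 + regime.m * np.sin(regime.omega * t)
    values = sinusoid * expit(regime.sigma_eps * x)
    # expit underflows to 0.0 only for |sigma_eps * x| beyond ~745; keep the
    # open-interval guarantee even then.
    tiny = np.finfo(float).tiny
    np.maximum(values, tiny, out=values)
    values.setflags(write=False)
    x.setflags(write=False)
    return TemperatureSeries(values=values, noise_draws=x, regime=regime)
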