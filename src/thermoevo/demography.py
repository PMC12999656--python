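"""Temperature-dependent demographic rates.

Two fixed thermal performance curves drive the ecology: a saturating
exponential intrinsic growth rate

    r(tau) = r0 * exp(-c / tau) + r1,

which is strictly increasing on (0, 1) and bounded below by ``r1``, and a
bell-shaped (Gaussian-in-temperature) carrying capacity

    k(tau) = k0 * exp(-(tau - tau_m)^2 / sigma_k),

peaking at ``k(tau_m) = k0``.  Temperatures live on the open unit interval
(critical thermal limits fixed at 0 and 1), so the essential singularity of
``exp(-c/tau)`` at tau = 0 is unreachable; a guard raises on ``tau <= 0``.

Neither curve evolves: the heritable trait in this model is the competition
TPC (see :mod:`thermoevo.competition_tpc`), not r or k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "CapacityParams",
    "DemographyParams",
    "growth_rate",
    "carrying_capacity",
]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the saturating-exponential growth-rate curve."""

    r0: float = 0.1
    c: float = 0.1
    r1: float = 0.1

    def __post_init__(self) -> None:
        for name in ("r0", "c", "r1"):
            v = getattr(self, name)
            if not v > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class CapacityParams:
    """Parameters of the bell-shaped carrying-capacity curve.

    ``ctau_min`` / ``ctau_max`` are the critical thermal limits; they are
    fixed constants carried for reporting only.
    """

    k0: float = 2.0
    tau_m: float = 0.5
    sigma_k: float = 0.05
    ctau_min: float = 0.0
    ctau_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.k0 > 0.0:
            raise ValueError(f"k0 must be strictly positive, got {self.k0}")
        if not self.sigma_k > 0.0:
            raise ValueError(f"sigma_k must be strictly positive, got {self.sigma_k}")
        if not 0.0 < self.tau_m < 1.0:
            raise ValueError(f"tau_m must lie in (0, 1), got {self.tau_m}")
        if (self.ctau_min, self.ctau_max) != (0.0, 1.0):
            raise ValueError("critical thermal limits are fixed at 0 and 1")


@dataclass(frozen=True)
class DemographyParams:
    """Bundle of the two fixed demographic TPCs."""

    growth: GrowthParams = GrowthParams()
    capacity: CapacityParams = CapacityParams()


def _check_tau(tau: np.ndarray) -> None:
    if np.any(tau <= 0.0) or np.any(tau >= 1.0):
        raise ValueError("temperature must lie strictly in (0, 1)")


def growth_rate(tau, p: GrowthParams = GrowthParams()):
    """Intrinsic growth rate ``r0 exp(-c/tau) + r1`` at temperature(s) *tau*."""
    tau = np.asarray(tau, dtype=float)
    _check_tau(tau)
    out = p.r0 * np.exp(-p.c / tau) + p.r1
    return out if out.ndim else float(out)


def carrying_capacity(tau, p: CapacityParams = CapacityParams()):
    """Carrying capacity ``k0 exp(-(tau - tau_m)^2 / sigma_k)`` at *tau*."""
    tau = np.asarray(tau, dtype=float)
    _check_tau(tau)
    out = p.k0 * np.exp(-((tau - p.tau_m) ** 2) / p.sigma_k)
    return out if out.ndim else float(out)
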