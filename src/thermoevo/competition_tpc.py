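"""Beta-density competition thermal performance curves.

The competitive performance of a type at temperature ``tau`` in (0, 1) is a
beta probability density ``beta(tau; mu, s)`` parameterized by its mean
``mu`` and a scaling parameter ``s`` that controls breadth.  We use the
standard beta shape parameters

    a = mu / s,    b = (1 - mu) / s,

the unique choice that reproduces both derived statistics used throughout:
the mode (thermal optimum for interior-unimodal curves)

    tau_opt = (a - 1) / (a + b - 2) = (mu - s) / (1 - 2 s)

and the variance (squared performance breadth)

    sigma^2 = a b / ((a + b)^2 (a + b + 1)) = s mu (1 - mu) / (s + 1).

Because every density integrates to one, broader curves are flatter: the
generalist-specialist trade-off is built in.

Competition coefficients between a resident (shape ``N``) and a rare
mutant (shape ``M``) are density ratios at the current temperature:

    alpha_MN(tau) = beta_N(tau) / beta_M(tau),   alpha_NM = 1 / alpha_MN,

computed as a difference of log-densities then exponentiated, so the
reciprocity ``alpha_MN * alpha_NM = 1`` holds to machine precision and
boundary-divergent densities do not overflow prematurely.

Shape taxonomy (from the beta shape parameters):

* ``a > 1`` and ``b > 1``  -> interior-unimodal (specialist/generalist hump);
* ``a <= 1 < b``           -> right-skewed J (monotone decreasing, peak at
  the cold boundary, tau_opt = 0);
* ``b <= 1 < a``           -> left-skewed J (peak at the hot boundary);
* ``a <= 1`` and ``b <= 1``-> U-shaped (mass at both extremes; the optimum
  is degenerate and flagged as such).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import betaln

__all__ = [
    "TPCShape",
    "ShapeClass",
    "CompetitionCoefficients",
    "OptimumResult",
    "log_beta_density",
    "beta_density",
    "tpc_optimum",
    "tpc_breadth",
    "tpc_breadth_squared",
    "classify_shape",
    "competition_coefficients",
]

_SYMMETRY_TOL = 1e-12  # robust to serialization round-trips of mu = 0.5
_LOG_RATIO_CAP = 700.0  # exp overflow guard for density ratios


@dataclass(frozen=True)
class TPCShape:
    """Competition-TPC shape: mean ``mu`` in (0,1), scaling ``s > 0``."""

    mu: float
    s: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if not self.s > 0.0:
            raise ValueError(f"s must be strictly positive, got {self.s}")

    @property
    def a(self) -> float:
        """First standard beta shape parameter, mu / s."""
        return self.mu / self.s

    @property
    def b(self) -> float:
        """Second standard beta shape parameter, (1 - mu) / s."""
        return (1.0 - self.mu) / self.s


@dataclass(frozen=True)
class ShapeClass:
    """Qualitative TPC shape, determined solely by (mu, s)."""

    label: str  # one of the _LABELS below
    symmetric: bool

    _LABELS = ("unimodal-interior", "right-skewed-J", "left-skewed-J", "U-shaped")


class CompetitionCoefficients(NamedTuple):
    """Reciprocal temperature-dependent competition coefficients."""

    alpha_MN: float  # effect of residents on mutants
    alpha_NM: float  # effect of mutants on residents


class OptimumResult(NamedTuple):
    value: float
    degenerate: bool


def log_beta_density(tau, shape: TPCShape):
    """Log of the beta density ``beta(tau; mu, s)``; vectorized over *tau*."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0.0) or np.any(tau >= 1.0):
        raise ValueError("tau must lie strictly in (0, 1)")
    a, b = shape.a, shape.b
    out = (a - 1.0) * np.log(tau) + (b - 1.0) * np.log1p(-tau) - betaln(a, b)
    return out if out.ndim else float(out)


def beta_density(tau, shape: TPCShape):
    """Beta density (the competition TPC) evaluated at *tau* in (0, 1)."""
    return np.exp(log_beta_density(tau, shape))


def classify_shape(shape: TPCShape) -> ShapeClass:
    """Classify the TPC by its beta shape parameters (see module docstring)."""
    a, b = shape.a, shape.b
    if a > 1.0 and b > 1.0:
        label = "unimodal-interior"
    elif a <= 1.0 < b:
        label = "right-skewed-J"
    elif b <= 1.0 < a:
        label = "left-skewed-J"
    else:  # a <= 1 and b <= 1 (includes the flat a = b = 1 case)
        label = "U-shaped"
    return ShapeClass(label=label, symmetric=abs(shape.mu - 0.5) < _SYMMETRY_TOL)


def tpc_optimum(shape: TPCShape, *, full: bool = False):
    """Thermal optimum of the competition TPC.

    Interior-unimodal curves have their mode at ``(mu - s) / (1 - 2s)``;
    J-shaped curves peak at the corresponding boundary (0 for right-skewed,
    1 for left-skewed).  U-shaped curves diverge at both boundaries; the
    boundary with the faster-diverging density is reported together with a
    degeneracy flag (set ``full=True`` to receive it).
    """
    cls = classify_shape(shape)
    degenerate = False
    if cls.label == "unimodal-interior":
        value = (shape.mu - shape.s) / (1.0 - 2.0 * shape.s)
    elif cls.label == "right-skewed-J":
        value = 0.0
    elif cls.label == "left-skewed-J":
        value = 1.0
    else:  # U-shaped: smaller shape parameter diverges faster at its boundary
        value = 0.0 if shape.a <= shape.b else 1.0
        degenerate = True
    if full:
        return OptimumResult(value=value, degenerate=degenerate)
    return value


def tpc_breadth_squared(shape: TPCShape) -> float:
    """Squared performance breadth, ``s mu (1 - mu) / (s + 1)`` (the variance)."""
    return shape.s * shape.mu * (1.0 - shape.mu) / (shape.s + 1.0)


def tpc_breadth(shape: TPCShape) -> float:
    """Performance breadth, ``sqrt(s mu (1 - mu) / (s + 1))``."""
    return math.sqrt(tpc_breadth_squared(shape))


def competition_coefficients(
    tau: float, resident: TPCShape, mutant: TPCShape
) -> CompetitionCoefficients:
    """Density-ratio competition coefficients at temperature *tau*.

    ``alpha_MN = beta_resident(tau) / beta_mutant(tau)`` and its exact
    reciprocal.  Identical shapes give (1, 1) exactly.
    """
    if resident == mutant:
        return CompetitionCoefficients(1.0, 1.0)
    log_ratio = log_beta_density(tau, resident) - log_beta_density(tau, mutant)
    if not math.isfinite(log_ratio):
        raise FloatingPointError(
            f"competition TPC density ratio is not finite at tau={tau} "
            f"(resident={resident}, mutant={mutant})"
        )
    if abs(log_ratio) > _LOG_RATIO_CAP:
        raise FloatingPointError(
            f"competition coefficient out of double range at tau={tau}: "
            f"log ratio {log_ratio:.1f} (resident={resident}, mutant={mutant})"
        )
    alpha_mn = math.exp(log_ratio)
    return CompetitionCoefficients(alpha_mn, 1.0 / alpha_mn)
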