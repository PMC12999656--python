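"""Canonical adaptive dynamics in the TPC trait plane.

Gradual evolution of the competition-TPC shape (mu, s) follows the
canonical equations

    d(mu)/dt = (1/2) * Ne * [E @ g]_mu,
    d(s)/dt  = (1/2) * Ne * [E @ g]_s,

where ``g = (g_mu, g_s)`` are the selection gradients, ``Ne`` the long-run
average resident population size and ``E`` the 2x2 mutational covariance
matrix (identity by default: independent mutations in mu and s).  The 1/2
accounts for the fraction of favourable mutations lost to drift while
rare; absolute time units are therefore arbitrary and only endpoints and
signs of the flow are meaningful.

An evolutionary singularity is a joint root of both gradients.  It is
located by a damped Newton iteration on the gradient map (FD Jacobian),
with explicit-Euler integration of the canonical equations as a fallback
and for trajectory output.  Classification:

* convergence stability — all eigenvalues of the Jacobian of the canonical
  vector field (in the *resident* traits) have negative real part;
* evolutionary stability (ESS) — the Hessian of mutant fitness at the
  singularity is negative definite;
* CSS — both, the end point of gradual evolution.

Traits are confined to the admissible box mu in [0.01, 0.99],
s in [0.005, 1.99].  Convergence onto the box boundary is a first-class
outcome, not an error: in a constant thermal environment selection drives
s (and with it the performance breadth) to zero, which the finite box
renders as boundary convergence at s_min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .competition_tpc import (
    ShapeClass,
    TPCShape,
    classify_shape,
    tpc_breadth,
    tpc_optimum,
)
from .demography import DemographyParams
from .invasion import FitnessHessian, InvasionConfig, ResidentContext, resident_context
from .thermal_env import ThermalRegime

__all__ = [
    "CanonicalConfig",
    "SingularityReport",
    "SingularitySearchError",
    "TRAIT_BOX",
    "canonical_trajectory",
    "nullclines",
    "find_singularity",
    "classify_singularity",
]

# admissible (mu, s) box: (mu_min, mu_max, s_min, s_max)
TRAIT_BOX = (0.01, 0.99, 0.005, 1.99)

_JAC_STEP = 1e-3  # FD step for Jacobians of the gradient map in resident traits


class SingularitySearchError(RuntimeError):
    """Raised when neither Newton nor canonical continuation converges."""


@dataclass(frozen=True)
class CanonicalConfig:
    """Controls for canonical-equation integration and classification.

    ``E`` is the mutational covariance matrix stored as a nested tuple so
    the config stays hashable; it must be symmetric positive definite.
    """

    E: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    step_eta: float = 0.05
    max_iters: int = 2000
    grad_tol: float = 1e-3

    def __post_init__(self) -> None:
        m = self.E_matrix
        if not np.allclose(m, m.T):
            raise ValueError("mutational covariance E must be symmetric")
        if np.any(np.linalg.eigvalsh(m) <= 0.0):
            raise ValueError("mutational covariance E must be positive definite")
        if self.step_eta <= 0.0 or self.grad_tol <= 0.0 or self.max_iters < 1:
            raise ValueError("step_eta, grad_tol must be > 0 and max_iters >= 1")

    @property
    def E_matrix(self) -> np.ndarray:
        return np.asarray(self.E, dtype=float)


@dataclass(frozen=True)
class SingularityReport:
    """A located singular strategy with its full classification."""

    mu_star: float
    s_star: float
    tau_opt_star: float
    breadth_star: float
    shape_class: ShapeClass
    jacobian_eigs: tuple[complex, complex]
    hessian: FitnessHessian
    verdict: str  # CSS | ESS-only | convergence-stable-only (branching candidate) | repeller
    residual: float  # gradient norm over the free (non-clamped) coordinates
    boundary_converged: bool = False
    clamped: tuple[str, ...] = ()
    g_s_at_boundary: Optional[float] = None

    @property
    def shape(self) -> TPCShape:
        return TPCShape(self.mu_star, self.s_star)

    def to_dict(self) -> dict:
        return {
            "mu_star": self.mu_star,
            "s_star": self.s_star,
            "tau_opt_star": self.tau_opt_star,
            "breadth_star": self.breadth_star,
            "breadth_sq_star": self.breadth_star**2,
            "shape_class": self.shape_class.label,
            "symmetric": self.shape_class.symmetric,
            "jacobian_eigs": [[z.real, z.imag] for z in self.jacobian_eigs],
            "hessian": self.hessian.entries.tolist(),
            "hessian_eigs": self.hessian.eigenvalues.tolist(),
            "verdict": self.verdict,
            "residual": self.residual,
            "boundary_converged": self.boundary_converged,
            "clamped": list(self.clamped),
            "g_s_at_boundary": self.g_s_at_boundary,
        }


def _project(x: np.ndarray) -> np.ndarray:
    lo = np.array([TRAIT_BOX[0], TRAIT_BOX[2]])
    hi = np.array([TRAIT_BOX[1], TRAIT_BOX[3]])
    return np.clip(x, lo, hi)


def _grad(ctx: ResidentContext, x: np.ndarray) -> np.ndarray:
    return ctx.gradient(TPCShape(float(x[0]), float(x[1]))).as_array()


def _grad_jacobian(ctx: ResidentContext, x: np.ndarray, h: float = _JAC_STEP) -> np.ndarray:
    """Central-FD Jacobian of the gradient map in the resident traits."""
    J = np.empty((2, 2))
    for j in range(2):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (_grad(ctx, _project(xp)) - _grad(ctx, _project(xm))) / (
            _project(xp)[j] - _project(xm)[j]
        )
    return J


# largest trait-space displacement allowed per Euler step; keeps the flow
# well resolved where gradients are steep (small s) without a norm test,
# which would wrongly freeze flows whose gradient grows along the path
# (the boundary-convergence case).
_MAX_EULER_STEP = 0.02


def canonical_trajectory(
    start: TPCShape,
    regime: ThermalRegime,
    params: DemographyParams,
    inv_cfg: InvasionConfig = InvasionConfig(),
    can_cfg: CanonicalConfig = CanonicalConfig(),
) -> list[TPCShape]:
    """Explicit-Euler trait trajectory of the canonical equations.

    Stops when the gradient norm drops below ``grad_tol``, when the state
    is pinned on the admissible-box boundary with an outward flow, or
    after ``max_iters`` steps.  Each Euler displacement is capped at a
    small trait-space length so steep gradients (small s) cannot fling
    the state across the box.
    """
    ctx = resident_context(regime, params, inv_cfg)
    E = can_cfg.E_matrix
    ne = ctx.effective_popsize
    x = np.array([start.mu, start.s], dtype=float)
    path = [TPCShape(*x)]
    for _ in range(can_cfg.max_iters):
        g = _grad(ctx, x)
        if np.linalg.norm(g) < can_cfg.grad_tol:
            break
        step = can_cfg.step_eta * 0.5 * ne * (E @ g)
        norm = float(np.linalg.norm(step))
        if norm > _MAX_EULER_STEP:
            step *= _MAX_EULER_STEP / norm
        x_new = _project(x + step)
        if np.linalg.norm(x_new - x) < 1e-12:  # pinned on the boundary
            break
        x = x_new
        path.append(TPCShape(*x))
    return path


def nullclines(
    regime: ThermalRegime,
    params: DemographyParams,
    inv_cfg: InvasionConfig,
    mu_grid: np.ndarray,
    s_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero contours of g_mu and g_s on a rectangular (mu, s) grid.

    Gradients are evaluated at every node; zero crossings are linearly
    interpolated along grid edges.  Returns two (n, 2) point arrays
    (columns mu, s); either may be empty if the sign never changes.
    """
    ctx = resident_context(regime, params, inv_cfg)
    mu_grid = np.asarray(mu_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    G = np.empty((len(mu_grid), len(s_grid), 2))
    for i, mu in enumerate(mu_grid):
        for j, s in enumerate(s_grid):
            G[i, j] = _grad(ctx, np.array([mu, s]))

    def contour(F: np.ndarray) -> np.ndarray:
        pts = []
        # horizontal edges (vary mu)
        for i in range(len(mu_grid) - 1):
            for j in range(len(s_grid)):
                f0, f1 = F[i, j], F[i + 1, j]
                if f0 == 0.0 or f0 * f1 < 0.0:
                    w = f0 / (f0 - f1) if f0 != f1 else 0.0
                    pts.append((mu_grid[i] + w * (mu_grid[i + 1] - mu_grid[i]), s_grid[j]))
        # vertical edges (vary s)
        for i in range(len(mu_grid)):
            for j in range(len(s_grid) - 1):
                f0, f1 = F[i, j], F[i, j + 1]
                if f0 == 0.0 or f0 * f1 < 0.0:
                    w = f0 / (f0 - f1) if f0 != f1 else 0.0
                    pts.append((mu_grid[i], s_grid[j] + w * (s_grid[j + 1] - s_grid[j])))
        return np.array(pts).reshape(-1, 2)

    return contour(G[:, :, 0]), contour(G[:, :, 1])


def _newton(
    ctx: ResidentContext, x0: np.ndarray, tol: float, max_iters: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Damped, box-projected Newton on the gradient map; returns (x, g(x))."""
    x = _project(x0.astype(float))
    g = _grad(ctx, x)
    for _ in range(max_iters):
        if np.linalg.norm(g) < tol:
            break
        J = _grad_jacobian(ctx, x)
        try:
            dx = np.linalg.solve(J, -g)
        except np.linalg.LinAlgError:
            dx = -g
        lam, improved = 1.0, False
        for _half in range(25):
            x_new = _project(x + lam * dx)
            g_new = _grad(ctx, x_new)
            if np.linalg.norm(g_new) < np.linalg.norm(g):
                improved = True
                break
            lam *= 0.5
        if not improved:
            break
        x, g = x_new, g_new
    return x, g


def _interior(x: np.ndarray, margin: float = 1e-9) -> bool:
    return bool(
        TRAIT_BOX[0] + margin < x[0] < TRAIT_BOX[1] - margin
        and TRAIT_BOX[2] + margin < x[1] < TRAIT_BOX[3] - margin
    )


def _solve_mu_on_boundary(ctx: ResidentContext, mu0: float, s_fixed: float, tol: float) -> float:
    """1-D Newton for g_mu = 0 at fixed s (boundary-convergence case)."""
    mu = float(np.clip(mu0, TRAIT_BOX[0], TRAIT_BOX[1]))
    h = _JAC_STEP
    for _ in range(60):
        g = _grad(ctx, np.array([mu, s_fixed]))[0]
        if abs(g) < tol:
            break
        dmu_g = (
            _grad(ctx, np.array([min(mu + h, TRAIT_BOX[1]), s_fixed]))[0]
            - _grad(ctx, np.array([max(mu - h, TRAIT_BOX[0]), s_fixed]))[0]
        ) / (min(mu + h, TRAIT_BOX[1]) - max(mu - h, TRAIT_BOX[0]))
        if dmu_g == 0.0:
            break
        step = -g / dmu_g
        mu = float(np.clip(mu + np.clip(step, -0.1, 0.1), TRAIT_BOX[0], TRAIT_BOX[1]))
    return mu


def find_singularity(
    initial_guess: TPCShape,
    regime: ThermalRegime,
    params: DemographyParams,
    inv_cfg: InvasionConfig = InvasionConfig(),
    can_cfg: CanonicalConfig = CanonicalConfig(),
) -> SingularityReport:
    """Locate and classify an evolutionary singularity.

    Damped Newton refines the joint root of (g_mu, g_s), starting from the
    guess and a handful of standard interior points; if no interior root is
    found, a canonical-equation continuation from the guess adjudicates
    boundary convergence.  Convergence onto an s box face (selection for
    ever-narrower, or runaway broader, TPCs) yields a boundary report with
    g_mu solved to zero at the clamped s.
    """
    ctx = resident_context(regime, params, inv_cfg)
    # Newton iterates to well below grad_tol when it can; grad_tol remains
    # the acceptance threshold for the report.
    tol_inner = min(can_cfg.grad_tol * 1e-3, 1e-6)
    # Multi-start: the density-ratio model has a secondary runaway basin
    # toward very broad (boundary-divergent) TPCs, so a single bad start can
    # miss an interior singularity that is locally convergence stable.
    starts = [
        (initial_guess.mu, initial_guess.s),
        (initial_guess.mu, 0.03),
        (initial_guess.mu, 0.012),
        (0.25, 0.03),
        (0.25, 0.012),
        (0.15, 0.05),
        (0.2, 0.08),
    ]
    for mu0, s0 in dict.fromkeys(starts):
        x, g = _newton(ctx, np.array([mu0, s0]), tol_inner)
        if np.linalg.norm(g) < can_cfg.grad_tol and _interior(x):
            return _classify(
                ctx, TPCShape(float(x[0]), float(x[1])), can_cfg,
                residual=float(np.linalg.norm(g)),
            )

    # Newton failed or stalled on the box: let the canonical flow decide
    # between an interior basin and genuine boundary convergence.  A loose
    # gradient tolerance suffices because Newton polishes afterwards.
    flow_cfg = dataclasses.replace(
        can_cfg, grad_tol=max(can_cfg.grad_tol, 0.02), max_iters=500
    )
    path = canonical_trajectory(initial_guess, regime, params, inv_cfg, flow_cfg)
    end = np.array([path[-1].mu, path[-1].s])
    g_end = _grad(ctx, end)

    if _interior(end) or np.linalg.norm(g_end) < flow_cfg.grad_tol:
        x, g = _newton(ctx, end, tol_inner)
        if np.linalg.norm(g) < can_cfg.grad_tol and _interior(x):
            return _classify(
                ctx, TPCShape(float(x[0]), float(x[1])), can_cfg,
                residual=float(np.linalg.norm(g)),
            )
        end, g_end = x, g

    # pinned on a box face with outward flow: boundary convergence
    s_pinned = (end[1] <= TRAIT_BOX[2] + 1e-9 and g_end[1] < 0.0) or (
        end[1] >= TRAIT_BOX[3] - 1e-9 and g_end[1] > 0.0
    )
    if s_pinned:
        s_fix = TRAIT_BOX[2] if g_end[1] < 0.0 else TRAIT_BOX[3]
        mu = _solve_mu_on_boundary(ctx, float(end[0]), s_fix, tol_inner)
        g_b = _grad(ctx, np.array([mu, s_fix]))
        if abs(g_b[0]) >= can_cfg.grad_tol:
            raise SingularitySearchError(
                f"boundary continuation failed: |g_mu|={abs(g_b[0]):.3g} at s={s_fix}"
            )
        return _classify(
            ctx,
            TPCShape(mu, s_fix),
            can_cfg,
            residual=abs(g_b[0]),
            boundary=True,
            clamped=("s",),
            g_s_boundary=float(g_b[1]),
        )

    raise SingularitySearchError(
        f"no singularity found from guess ({initial_guess.mu}, {initial_guess.s}); "
        f"flow endpoint ({end[0]:.4f}, {end[1]:.4f}) with |g|={np.linalg.norm(g_end):.3g}"
    )


def _classify(
    ctx: ResidentContext,
    point: TPCShape,
    can_cfg: CanonicalConfig,
    residual: float,
    boundary: bool = False,
    clamped: tuple[str, ...] = (),
    g_s_boundary: Optional[float] = None,
) -> SingularityReport:
    hess = ctx.hessian(point)
    x = np.array([point.mu, point.s])
    dGdx = _grad_jacobian(ctx, x)
    J = 0.5 * ctx.effective_popsize * (can_cfg.E_matrix @ dGdx)
    eigs = np.linalg.eigvals(J)
    conv_stable = bool(np.all(eigs.real < 0.0))
    ess = hess.negative_definite
    if boundary:
        # only mu is free; assess stability along the boundary
        conv_stable = bool(J[0, 0] < 0.0)
        ess = bool(hess.entries[0, 0] < 0.0)
    if conv_stable and ess:
        verdict = "CSS"
    elif ess:
        verdict = "ESS-only"
    elif conv_stable:
        verdict = "convergence-stable-only (branching candidate)"
    else:
        verdict = "repeller"
    return SingularityReport(
        mu_star=point.mu,
        s_star=point.s,
        tau_opt_star=float(tpc_optimum(point)),
        breadth_star=tpc_breadth(point),
        shape_class=classify_shape(point),
        jacobian_eigs=(complex(eigs[0]), complex(eigs[1])),
        hessian=hess,
        verdict=verdict,
        residual=residual,
        boundary_converged=boundary,
        clamped=clamped,
        g_s_at_boundary=g_s_boundary,
    )


def classify_singularity(
    point: TPCShape,
    regime: ThermalRegime,
    params: DemographyParams,
    inv_cfg: InvasionConfig = InvasionConfig(),
    can_cfg: CanonicalConfig = CanonicalConfig(),
) -> SingularityReport:
    """Classify an already-located singular point (gradient must be small)."""
    ctx = resident_context(regime, params, inv_cfg)
    g = _grad(ctx, np.array([point.mu, point.s]))
    if np.linalg.norm(g) >= can_cfg.grad_tol:
        raise ValueError(
            f"point ({point.mu}, {point.s}) is not singular: |g|={np.linalg.norm(g):.3g} "
            f">= grad_tol={can_cfg.grad_tol}"
        )
    return _classify(ctx, point, can_cfg, residual=float(np.linalg.norm(g)))
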