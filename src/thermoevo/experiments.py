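"""Orchestration of the standard computational experiments.

Three entry points:

* :func:`run_sweep` — evolutionarily singular TPC statistics over a
  (sigma_eps, omega) grid at fixed sine magnitude m, with serpentine
  warm-starting and per-cell seeds derived deterministically from a master
  seed;
* :func:`temperature_histogram_with_tpc` — a normalized long-run
  temperature histogram side by side with the singular TPC density of the
  same regime;
* :func:`preset` — named parameter bundles for the reference regimes
  (low/high-noise vector fields, population-dynamics comparisons, sweep
  defaults, histogram panels).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive import (
    CanonicalConfig,
    SingularityReport,
    SingularitySearchError,
    find_singularity,
)
from .competition_tpc import TPCShape, beta_density
from .demography import DemographyParams
from .invasion import InvasionConfig
from .thermal_env import ThermalRegime, generate_temperature

__all__ = [
    "SweepSpec",
    "SweepError",
    "run_sweep",
    "temperature_histogram_with_tpc",
    "preset",
    "PRESET_NAMES",
]

logger = logging.getLogger(__name__)

_SWEEP_COLUMNS = [
    "sigma_eps",
    "omega",
    "mu_star",
    "s_star",
    "tau_opt_star",
    "breadth_star",
    "breadth_sq_star",
    "shape_class",
    "verdict",
    "residual",
    "boundary",
    "seed",
]


class SweepError(RuntimeError):
    """Raised when too many sweep cells fail; carries the partial table."""

    def __init__(self, message: str, partial: pd.DataFrame):
        super().__init__(message)
        self.partial = partial


@dataclass(frozen=True)
class SweepSpec:
    """A (sigma_eps, omega) grid sweep at fixed sine magnitude m."""

    sigma_eps_grid: tuple[float, ...]
    omega_grid: tuple[float, ...]
    m: float = 0.25
    tau0: float = 0.5
    params: DemographyParams = DemographyParams()
    inv_cfg: InvasionConfig = InvasionConfig(horizon_L=20_000, burn_in=1000)
    can_cfg: CanonicalConfig = CanonicalConfig()
    master_seed: int = 0
    continuation: bool = True
    initial_guess: TPCShape = TPCShape(0.25, 0.08)

    def __post_init__(self) -> None:
        sg = np.asarray(self.sigma_eps_grid, dtype=float)
        og = np.asarray(self.omega_grid, dtype=float)
        if sg.size == 0 or og.size == 0:
            raise ValueError("sweep grids must be non-empty")
        if np.any(np.diff(sg) <= 0) or np.any(np.diff(og) <= 0):
            raise ValueError("sweep grids must be strictly increasing")
        if sg[0] < 0.0 or sg[-1] > 2.0:
            raise ValueError("sigma_eps grid must lie within [0, 2]")
        if og[0] <= 0.0 or og[-1] > 2.0 * math.pi + 1e-12:
            raise ValueError("omega grid must lie within (0, 2*pi]")


def _cell_seed(master: int, i: int, j: int) -> int:
    """Deterministic per-cell noise seed below 2**31."""
    return int(np.random.SeedSequence([master, i, j]).generate_state(1)[0] % 2**31)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Singularity search on every (sigma_eps, omega) cell of the grid.

    Cells are visited in serpentine order so that, with continuation
    enabled, each search warm-starts from its predecessor's singular
    strategy.  Failed cells are recorded with verdict ``failed`` rather
    than aborting; more than 20% failures raises :class:`SweepError`
    carrying the partial table.
    """
    rows = []
    n_failed = 0
    guess = spec.initial_guess
    for i, sig in enumerate(spec.sigma_eps_grid):
        omega_order = (
            list(enumerate(spec.omega_grid))
            if i % 2 == 0
            else list(enumerate(spec.omega_grid))[::-1]
        )
        for j, omega in omega_order:
            seed = _cell_seed(spec.master_seed, i, j)
            regime = ThermalRegime(
                tau0=spec.tau0, m=spec.m, omega=float(omega),
                sigma_eps=float(sig), seed=seed,
            )
            cfg = InvasionConfig(
                horizon_L=spec.inv_cfg.horizon_L,
                burn_in=spec.inv_cfg.burn_in,
                fd_step=spec.inv_cfg.fd_step,
                noise_seed=seed,
            )
            try:
                rep = find_singularity(guess, regime, spec.params, cfg, spec.can_cfg)
            except SingularitySearchError as exc:
                logger.warning("cell (%g, %g) failed: %s", sig, omega, exc)
                n_failed += 1
                rows.append(
                    dict.fromkeys(_SWEEP_COLUMNS)
                    | {"sigma_eps": sig, "omega": omega, "verdict": "failed", "seed": seed}
                )
                continue
            rows.append(
                {
                    "sigma_eps": sig,
                    "omega": omega,
                    "mu_star": rep.mu_star,
                    "s_star": rep.s_star,
                    "tau_opt_star": rep.tau_opt_star,
                    "breadth_star": rep.breadth_star,
                    "breadth_sq_star": rep.breadth_star**2,
                    "shape_class": rep.shape_class.label,
                    "verdict": rep.verdict,
                    "residual": rep.residual,
                    "boundary": rep.boundary_converged,
                    "seed": seed,
                }
            )
            if spec.continuation and not rep.boundary_converged:
                guess = TPCShape(rep.mu_star, max(rep.s_star, 0.01))
    table = pd.DataFrame(rows, columns=_SWEEP_COLUMNS)
    n_cells = len(spec.sigma_eps_grid) * len(spec.omega_grid)
    if n_failed > 0.2 * n_cells:
        raise SweepError(
            f"{n_failed}/{n_cells} sweep cells failed", partial=table
        )
    return table


def temperature_histogram_with_tpc(
    regime: ThermalRegime,
    params: DemographyParams = DemographyParams(),
    inv_cfg: InvasionConfig = InvasionConfig(horizon_L=20_000, burn_in=1000),
    bins: int = 50,
    initial_guess: TPCShape = TPCShape(0.2, 0.08),
) -> tuple[pd.DataFrame, SingularityReport]:
    """Normalized temperature histogram plus the regime's singular TPC.

    Returns a table with columns (bin_center, frequency, tpc_density) —
    ``frequency`` is the per-bin probability mass (sums to one) — and the
    full singularity report.  A degenerate constant series collapses to a
    single occupied bin and triggers a warning.
    """
    if bins < 1:
        raise ValueError(f"bins must be positive, got {bins}")
    series = generate_temperature(regime, inv_cfg.horizon_L)
    values = series.values
    if np.ptp(values) < 1e-12:
        warnings.warn("temperature series is (numerically) constant; "
                      "histogram collapses to a single bin")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    freq = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    rep = find_singularity(initial_guess, regime, params, inv_cfg)
    dens = beta_density(centers, rep.shape)
    table = pd.DataFrame(
        {"bin_center": centers, "frequency": freq, "tpc_density": dens}
    )
    return table, rep


# --- presets -------------------------------------------------------------

_REFERENCE_DEMOGRAPHY = DemographyParams()  # r0=c=r1=0.1, k0=2, tau_m=0.5, sigma_k=0.05

PRESET_NAMES = (
    "fig2a",
    "fig2b",
    "fig3_low",
    "fig3_high",
    "fig4_m025",
    "fig4_m04",
    "fig5_top",
    "fig5_bottom",
)


def _sweep_defaults(m: float) -> SweepSpec:
    return SweepSpec(
        sigma_eps_grid=tuple(float(v) for v in np.linspace(0.2, 1.8, 8)),
        omega_grid=tuple(float(v) for v in np.linspace(math.pi / 4, 2 * math.pi, 8)),
        m=m,
    )


def preset(name: str):
    """Full experiment configuration for a named reference regime."""
    from .config import ExperimentConfig  # local import to avoid a cycle

    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    base = dict(tau0=0.5, m=0.25, omega=13 * math.pi / 20)
    thermal = {
        "fig2a": ThermalRegime(**base, sigma_eps=0.5),
        "fig2b": ThermalRegime(**base, sigma_eps=1.5),
        "fig3_low": ThermalRegime(**base, sigma_eps=0.5),
        "fig3_high": ThermalRegime(**base, sigma_eps=1.5),
        "fig4_m025": ThermalRegime(**base),
        "fig4_m04": ThermalRegime(tau0=0.5, m=0.4, omega=13 * math.pi / 20, sigma_eps=0.5),
        "fig5_top": ThermalRegime(tau0=0.5, m=0.4, omega=math.pi / 20, sigma_eps=0.0),
        "fig5_bottom": ThermalRegime(tau0=0.5, m=0.4, omega=math.pi / 20, sigma_eps=1.1282),
    }[name]
    sweep = None
    if name == "fig4_m025":
        sweep = _sweep_defaults(0.25)
    elif name == "fig4_m04":
        sweep = _sweep_defaults(0.4)
    return ExperimentConfig(
        thermal=thermal,
        growth=_REFERENCE_DEMOGRAPHY.growth,
        capacity=_REFERENCE_DEMOGRAPHY.capacity,
        invasion=InvasionConfig(),
        canonical=CanonicalConfig(),
        sweep=sweep,
    )
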