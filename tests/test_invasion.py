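import math

import numpy as np
import pytest
from oracle_utils import rare_mutant_fitness, score_function_gradient

from thermoevo import (
    InvasionConfig,
    TPCShape,
    ThermalRegime,
    fitness_hessian,
    invasion_fitness,
    selection_gradient,
)


def test_resident_neutrality(demo, fig2a_regime, fig2b_regime):
    """The resident is neutral against itself: lambda(x, x) telescopes to
    (log N_L - log N_burn)/window on a bounded attractor."""
    cfg = InvasionConfig(horizon_L=100_000, burn_in=1000, noise_seed=3)
    for regime in (fig2a_regime, fig2b_regime):
        for shape in (TPCShape(0.3, 0.06), TPCShape(0.15, 0.1)):
            assert abs(invasion_fitness(shape, shape, regime, demo, cfg)) < 1e-3


def test_common_random_numbers_bit_identical(demo, fig2a_regime, cfg_small):
    g1 = selection_gradient(TPCShape(0.3, 0.06), fig2a_regime, demo, cfg_small)
    g2 = selection_gradient(TPCShape(0.3, 0.06), fig2a_regime, demo, cfg_small)
    assert g1.g_mu == g2.g_mu and g1.g_s == g2.g_s


@pytest.mark.parametrize("trial", range(5))
def test_rare_mutant_oracle_equivalence(demo, cfg_small, trial):
    """Long-run averaging equals direct co-simulation of a rare mutant.

    Mutants are drawn close to the resident (the regime the FD stencils
    probe) so that lambda * window stays small and the mutant remains rare
    throughout: the co-simulation oracle is only valid in that limit.
    """
    rng = np.random.default_rng(100 + trial)
    resident = TPCShape(rng.uniform(0.15, 0.45), rng.uniform(0.03, 0.15))
    mutant = TPCShape(
        resident.mu + rng.uniform(-1e-4, 1e-4), resident.s * (1 + rng.uniform(-1e-3, 1e-3))
    )
    regime = ThermalRegime(
        tau0=0.5,
        m=rng.uniform(0.1, 0.4),
        omega=rng.uniform(0.3, 2 * math.pi),
        sigma_eps=rng.uniform(0.0, 1.5),
    )
    lam = invasion_fitness(resident, mutant, regime, demo, cfg_small)
    oracle = rare_mutant_fitness(resident, mutant, regime, demo, cfg_small)
    assert lam == pytest.approx(oracle, abs=1e-6)


def test_gradient_matches_score_function_oracle(demo, fig2a_regime, cfg_small):
    """FD gradients agree with the analytic (score-function) form obtained
    by differentiating the fitness average through the log-density, on a
    5x5 grid of residents."""
    for mu in np.linspace(0.15, 0.45, 5):
        for s in np.linspace(0.03, 0.2, 5):
            resident = TPCShape(float(mu), float(s))
            g = selection_gradient(resident, fig2a_regime, demo, cfg_small)
            o_mu, o_s = score_function_gradient(resident, fig2a_regime, demo, cfg_small)
            scale = max(abs(o_mu), abs(o_s))
            assert g.g_mu == pytest.approx(o_mu, abs=0.01 * scale)
            assert g.g_s == pytest.approx(o_s, abs=0.01 * scale)


def test_gradient_sign_points_toward_singularity(demo, fig2a_regime, cfg_small):
    """From a resident warmer than the singular strategy, selection pushes
    the TPC mean down."""
    g = selection_gradient(TPCShape(0.5, 0.1), fig2a_regime, demo, cfg_small)
    assert g.g_mu < 0


def test_hessian_step_robustness_and_symmetry(demo, fig2a_regime, cfg_small):
    """The FD Hessian is symmetric and stable under a halved step."""
    resident = TPCShape(0.2, 0.05)
    h1 = fitness_hessian(resident, fig2a_regime, demo, cfg_small)
    assert h1.entries[0, 1] == h1.entries[1, 0]
    cfg2 = InvasionConfig(
        horizon_L=cfg_small.horizon_L,
        burn_in=cfg_small.burn_in,
        fd_step=cfg_small.fd_step / 2,
        noise_seed=cfg_small.noise_seed,
    )
    h2 = fitness_hessian(resident, fig2a_regime, demo, cfg2)
    np.testing.assert_allclose(h1.entries, h2.entries, rtol=0.02)


def test_fd_step_bound_guard(demo, fig2a_regime):
    cfg = InvasionConfig(horizon_L=5000, burn_in=100, fd_step=0.01)
    with pytest.raises(ValueError):
        selection_gradient(TPCShape(0.995, 0.1), fig2a_regime, demo, cfg)
    with pytest.raises(ValueError):
        InvasionConfig(horizon_L=100, burn_in=100)
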