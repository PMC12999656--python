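import math

import numpy as np
import pytest

from thermoevo import (
    CanonicalConfig,
    TPCShape,
    ThermalRegime,
    canonical_trajectory,
    classify_singularity,
    find_singularity,
    nullclines,
)
from thermoevo.adaptive import TRAIT_BOX


def random_spd(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(2, 2))
    M = A @ A.T + 0.3 * np.eye(2)
    return tuple(tuple(float(v) for v in row) for row in M)


@pytest.fixture(scope="module")
def fig2a_report(demo, fig2a_regime, cfg_small):
    return find_singularity(TPCShape(0.25, 0.08), fig2a_regime, demo, cfg_small)


def test_interior_singularity_found_and_css(fig2a_report):
    rep = fig2a_report
    assert not rep.boundary_converged
    assert rep.residual < 1e-3
    assert rep.verdict == "CSS"
    assert np.all(rep.hessian.eigenvalues < 0)
    assert all(z.real < 0 for z in rep.jacobian_eigs)
    # noise shifts the optimum below the mean environmental temperature
    assert rep.tau_opt_star < 0.25


def test_canonical_flow_reaches_singularity(demo, fig2a_regime, cfg_small, fig2a_report):
    path = canonical_trajectory(
        TPCShape(0.5, 0.3), fig2a_regime, demo, cfg_small,
        CanonicalConfig(grad_tol=5e-3, max_iters=3000),
    )
    end = path[-1]
    assert abs(end.mu - fig2a_report.mu_star) < 0.02
    assert abs(end.s - fig2a_report.s_star) < 0.02


def test_stationary_start_stays_put(demo, fig2a_regime, cfg_small, fig2a_report):
    path = canonical_trajectory(
        fig2a_report.shape, fig2a_regime, demo, cfg_small, CanonicalConfig()
    )
    assert len(path) <= 2  # gradient already below tolerance


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_singularity_invariant_under_mutational_covariance(
    demo, fig2a_regime, cfg_small, fig2a_report, seed
):
    """E rescales the flow but cannot move the root of the gradients, nor
    change convergence stability."""
    cfg_e = CanonicalConfig(E=random_spd(seed))
    rep = find_singularity(TPCShape(0.4, 0.15), fig2a_regime, demo, cfg_small, cfg_e)
    assert abs(rep.mu_star - fig2a_report.mu_star) < 0.005
    assert abs(rep.s_star - fig2a_report.s_star) < 0.005
    assert rep.verdict == fig2a_report.verdict


def test_nullclines_intersect_at_singularity(demo, fig2a_regime, cfg_small, fig2a_report):
    mu_grid = np.linspace(0.08, 0.45, 16)
    s_grid = np.linspace(0.01, 0.2, 14)
    c_mu, c_s = nullclines(fig2a_regime, demo, cfg_small, mu_grid, s_grid)
    assert len(c_mu) > 0 and len(c_s) > 0
    star = np.array([fig2a_report.mu_star, fig2a_report.s_star])
    for contour in (c_mu, c_s):
        d = np.min(np.linalg.norm(contour - star, axis=1))
        assert d < 0.02


def test_nullclines_empty_when_no_sign_change(demo, fig2a_regime, cfg_small):
    mu_grid = np.linspace(0.6, 0.8, 4)
    s_grid = np.linspace(0.3, 0.5, 4)
    c_mu, _ = nullclines(fig2a_regime, demo, cfg_small, mu_grid, s_grid)
    assert len(c_mu) == 0


def test_constant_environment_boundary_convergence(demo, cfg_small):
    """With a constant temperature the breadth collapses: boundary
    convergence at s_min with the optimum at the constant temperature."""
    regime = ThermalRegime(tau0=0.5, m=0.25, omega=2 * math.pi, sigma_eps=0.0)
    rep = find_singularity(TPCShape(0.25, 0.08), regime, demo, cfg_small)
    assert rep.boundary_converged
    assert rep.s_star == TRAIT_BOX[2]
    assert rep.g_s_at_boundary < 0
    assert rep.tau_opt_star == pytest.approx(0.25, abs=0.01)


def test_classification_is_pure_function_of_eigenvalues(fig2a_report):
    rep = fig2a_report
    conv = all(z.real < 0 for z in rep.jacobian_eigs)
    ess = bool(np.all(rep.hessian.eigenvalues < 0))
    expected = "CSS" if (conv and ess) else "other"
    assert (rep.verdict == "CSS") == (expected == "CSS")


def test_classify_rejects_non_singular_point(demo, fig2a_regime, cfg_small):
    with pytest.raises(ValueError):
        classify_singularity(TPCShape(0.5, 0.3), fig2a_regime, demo, cfg_small)


def test_classify_accepts_singular_point(demo, fig2a_regime, cfg_small, fig2a_report):
    rep = classify_singularity(
        fig2a_report.shape, fig2a_regime, demo, cfg_small
    )
    assert rep.verdict == fig2a_report.verdict


def test_report_serialization_round_trip(fig2a_report):
    d = fig2a_report.to_dict()
    assert d["verdict"] == fig2a_report.verdict
    assert d["mu_star"] == fig2a_report.mu_star
    assert d["breadth_sq_star"] == pytest.approx(fig2a_report.breadth_star**2)


def test_invalid_canonical_config():
    with pytest.raises(ValueError):
        CanonicalConfig(E=((1.0, 0.5), (0.4, 1.0)))  # asymmetric
    with pytest.raises(ValueError):
        CanonicalConfig(E=((1.0, 2.0), (2.0, 1.0)))  # not positive definite
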