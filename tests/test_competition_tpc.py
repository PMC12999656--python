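import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import beta as scipy_beta

from thermoevo import (
    TPCShape,
    beta_density,
    classify_shape,
    competition_coefficients,
    tpc_breadth,
    tpc_breadth_squared,
    tpc_optimum,
)

# Singular shapes and their derived statistics as printed alongside the
# reference histogram panels; these anchor the (mu, s) -> (a, b)
# parametrization.
CAPTION_CASES = [
    # (mu, s, tau_opt at 4 d.p., variance at 4 d.p.)
    (0.17, 0.09, 0.0976, 0.0117),
    (0.13, 0.06, 0.0795, 0.0064),
    (0.11, 0.05, 0.0667, 0.0047),
    (0.14, 0.14, 0.0, 0.0148),
    (0.11, 0.10, 0.0125, 0.0089),
    (0.10, 0.09, 0.0122, 0.0074),
]


@pytest.mark.parametrize("mu, s, tau_opt, variance", CAPTION_CASES)
def test_caption_optimum_and_variance(mu, s, tau_opt, variance):
    shape = TPCShape(mu, s)
    assert round(tpc_optimum(shape), 4) == pytest.approx(tau_opt, abs=5e-5)
    assert round(tpc_breadth_squared(shape), 4) == pytest.approx(variance, abs=5e-5)


def test_breadth_closed_form_and_limits():
    assert tpc_breadth(TPCShape(0.5, 1.0)) == pytest.approx(math.sqrt(0.125), rel=1e-12)
    assert tpc_breadth(TPCShape(0.3, 1e-8)) < 1e-4
    assert tpc_optimum(TPCShape(0.5, 0.1)) == pytest.approx(0.5, abs=1e-12)


@pytest.mark.parametrize(
    "mu, s, label, symmetric",
    [
        (0.17, 0.09, "unimodal-interior", False),
        (0.14, 0.14, "right-skewed-J", False),
        (0.86, 0.14, "left-skewed-J", False),
        (0.5, 0.6, "U-shaped", True),
        (0.5, 0.1, "unimodal-interior", True),
    ],
)
def test_shape_classification(mu, s, label, symmetric):
    cls = classify_shape(TPCShape(mu, s))
    assert cls.label == label
    assert cls.symmetric is symmetric


def test_u_shape_optimum_flagged_degenerate():
    res = tpc_optimum(TPCShape(0.4, 0.8), full=True)
    assert res.degenerate and res.value == 0.0
    res = tpc_optimum(TPCShape(0.6, 0.8), full=True)
    assert res.degenerate and res.value == 1.0


@pytest.mark.parametrize("mu, s", [(0.17, 0.09), (0.5, 0.6), (0.14, 0.14), (0.8, 0.3)])
def test_density_normalization_and_oracle(mu, s):
    """The TPC is a probability density; it matches scipy's beta density."""
    shape = TPCShape(mu, s)
    integral, _ = quad(lambda t: beta_density(t, shape), 0.0, 1.0, limit=200)
    assert integral == pytest.approx(1.0, abs=1e-6)
    taus = np.linspace(0.01, 0.99, 50)
    np.testing.assert_allclose(
        beta_density(taus, shape),
        scipy_beta.pdf(taus, shape.a, shape.b),
        rtol=1e-10,
    )


def test_mode_and_variance_match_density():
    """Grid argmax and numerical variance agree with the closed forms."""
    shape = TPCShape(0.17, 0.09)
    grid = np.linspace(1e-4, 1 - 1e-4, 200_001)
    argmax = grid[np.argmax(beta_density(grid, shape))]
    assert argmax == pytest.approx(tpc_optimum(shape), abs=1e-5)
    mean, _ = quad(lambda t: t * beta_density(t, shape), 0, 1, limit=200)
    var, _ = quad(lambda t: (t - mean) ** 2 * beta_density(t, shape), 0, 1, limit=200)
    assert var == pytest.approx(tpc_breadth_squared(shape), abs=1e-6)


def test_symmetric_shape_density_mirror():
    shape = TPCShape(0.5, 0.3)
    assert beta_density(0.3, shape) == pytest.approx(beta_density(0.7, shape), rel=1e-12)


def test_identical_shapes_give_unit_coefficients():
    c = competition_coefficients(0.37, TPCShape(0.3, 0.05), TPCShape(0.3, 0.05))
    assert c.alpha_MN == 1.0 and c.alpha_NM == 1.0


@settings(max_examples=80, derandomize=True)
@given(
    tau=st.floats(0.02, 0.98),
    mu1=st.floats(0.05, 0.95),
    s1=st.floats(0.01, 1.5),
    mu2=st.floats(0.05, 0.95),
    s2=st.floats(0.01, 1.5),
)
def test_reciprocity_property(tau, mu1, s1, mu2, s2):
    """alpha_MN * alpha_NM = 1 to machine precision for any pair."""
    c = competition_coefficients(tau, TPCShape(mu1, s1), TPCShape(mu2, s2))
    assert c.alpha_MN * c.alpha_NM == pytest.approx(1.0, rel=1e-12)


def test_coefficient_matches_independent_ratio():
    resident, mutant = TPCShape(0.30, 0.05), TPCShape(0.35, 0.05)
    c = competition_coefficients(0.30, resident, mutant)
    oracle = scipy_beta.pdf(0.30, resident.a, resident.b) / scipy_beta.pdf(
        0.30, mutant.a, mutant.b
    )
    assert c.alpha_MN == pytest.approx(oracle, rel=1e-10)


def test_narrow_shape_concentrates_mass():
    """As s -> 0 the density concentrates within mu +/- 3 breadths."""
    shape = TPCShape(0.3, 1e-3)
    lo = 0.3 - 3 * tpc_breadth(shape)
    hi = 0.3 + 3 * tpc_breadth(shape)
    mass, _ = quad(lambda t: beta_density(t, shape), lo, hi, limit=200)
    assert mass > 0.99


def test_domain_errors():
    with pytest.raises(ValueError):
        beta_density(0.0, TPCShape(0.3, 0.1))
    with pytest.raises(ValueError):
        TPCShape(0.0, 0.1)
    with pytest.raises(ValueError):
        TPCShape(0.5, 0.0)
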