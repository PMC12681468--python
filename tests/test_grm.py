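"""Psychometric kernel: GRM probabilities, information, EAP scoring, transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from sercat import (
    ItemParameters,
    QuadratureGrid,
    category_probabilities,
    eap_estimate,
    item_information,
    se_from_information,
    se_from_reliability,
    theta_from_tscore,
    tscore,
)
from sercat import test_information as total_information  # avoid pytest collection

from conftest import random_item, random_response_set


# ---------------------------------------------------------------------------
# parameter validation

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(item_id="x", alpha=0.0, betas=(0.0,)),
        dict(item_id="x", alpha=-1.0, betas=(0.0,)),
        dict(item_id="x", alpha=1.0, betas=()),
        dict(item_id="x", alpha=1.0, betas=(0.0, 0.0)),
        dict(item_id="x", alpha=1.0, betas=(1.0, 0.0)),
        dict(item_id="", alpha=1.0, betas=(0.0,)),
    ],
)
def test_invalid_item_parameters_rejected(kwargs):
    with pytest.raises(ValueError):
        ItemParameters(**kwargs)


# ---------------------------------------------------------------------------
# category probabilities

def test_binary_item_fifty_fifty_at_threshold():
    item = ItemParameters("b", alpha=1.7, betas=(0.8,))
    probs = category_probabilities(item, 0.8)
    assert probs == pytest.approx([0.5, 0.5], abs=1e-12)


def test_four_category_probabilities_known_values(poly_item):
    # logistic differences at theta=0 with alpha=2, betas=(-1, 0, 1):
    # P*(-1)=expit(2), P*(0)=0.5, P*(1)=expit(-2)
    probs = category_probabilities(poly_item, 0.0)
    assert probs == pytest.approx([0.1192, 0.3808, 0.3808, 0.1192], abs=5e-5)


def test_nonfinite_theta_rejected(poly_item):
    with pytest.raises(ValueError):
        category_probabilities(poly_item, float("nan"))
    with pytest.raises(ValueError):
        item_information(poly_item, float("inf"))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    theta=st.floats(-5, 5),
)
def test_probabilities_normalize_and_cumulatives_decrease(seed, theta):
    """P_k sum to 1 within 1e-12, all in (0,1); P*_k strictly decreasing in k."""
    item = random_item(np.random.default_rng(seed))
    probs = category_probabilities(item, theta)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(probs > 0) and np.all(probs < 1)
    pstar = expit(item.alpha * (theta - np.asarray(item.betas)))
    assert np.all(np.diff(pstar) < 0)


# ---------------------------------------------------------------------------
# information

def test_binary_information_is_alpha_sq_pq():
    """Two-category reduction: I(theta) = alpha^2 * p * q to machine precision."""
    for alpha, beta, theta in [(1.4, 0.5, 0.0), (2.2, -1.0, 1.3), (0.7, 2.0, 2.0)]:
        item = ItemParameters("b", alpha=alpha, betas=(beta,))
        p = expit(alpha * (theta - beta))
        assert item_information(item, theta) == pytest.approx(
            alpha**2 * p * (1 - p), rel=1e-12
        )


def test_information_vanishes_at_extremes(poly_item):
    assert item_information(poly_item, 40.0) == pytest.approx(0.0, abs=1e-12)
    assert item_information(poly_item, -40.0) == pytest.approx(0.0, abs=1e-12)


def _fd_information(item, theta, h=1e-4):
    """Oracle: expected negative second derivative of the log-likelihood."""
    p0 = category_probabilities(item, theta)
    lp = lambda t: np.log(category_probabilities(item, t))
    second = (lp(theta + h) - 2 * lp(theta) + lp(theta - h)) / h**2
    return float(-(p0 * second).sum())


@pytest.mark.parametrize("seed", range(30))
def test_information_matches_finite_difference_oracle(seed):
    rng = np.random.default_rng(seed)
    item = random_item(rng)
    theta = float(rng.uniform(-3, 3))
    assert item_information(item, theta) == pytest.approx(
        _fd_information(item, theta), abs=1e-5
    )


def test_test_information_is_additive(poly_item, binary_item, small_bank):
    theta = 0.3
    single = total_information([poly_item], theta)
    assert single == item_information(poly_item, theta)
    assert total_information([poly_item, poly_item], theta) == pytest.approx(2 * single, rel=1e-14)
    three = list(small_bank)[:3]
    assert total_information(three, theta) == pytest.approx(
        sum(item_information(it, theta) for it in three), rel=1e-14
    )
    with pytest.raises(ValueError):
        total_information([], theta)


# ---------------------------------------------------------------------------
# SE identities

def test_se_from_information_closed_forms():
    assert se_from_information(1.0) == 1.0
    assert se_from_information(4.0) == 0.5
    assert se_from_information(9.765625) == pytest.approx(0.32, abs=1e-15)
    for bad in (0.0, -1.0):
        with pytest.raises(ValueError):
            se_from_information(bad)


def test_se_from_reliability():
    """Reliability 0.90 with unit SD gives the conventional 0.32 threshold."""
    assert round(se_from_reliability(1.0, 0.90), 2) == 0.32
    assert se_from_reliability(1.0, 1.0) == 0.0
    assert se_from_reliability(10.0, 0.90) == pytest.approx(3.162, abs=5e-4)
    with pytest.raises(ValueError):
        se_from_reliability(1.0, 1.5)
    with pytest.raises(ValueError):
        se_from_reliability(1.0, -0.1)


def test_tscore_linear_map_and_inverse():
    assert tscore(0.0) == 50.0
    assert tscore(1.0) == 60.0
    assert tscore(-1.5) == 35.0
    for t in (-3.3, 0.0, 2.71):
        assert theta_from_tscore(tscore(t)) == pytest.approx(t, abs=1e-12)


# ---------------------------------------------------------------------------
# EAP estimation

def test_eap_empty_responses_recovers_prior(grid):
    est = eap_estimate([], grid)
    assert est.theta == pytest.approx(0.0, abs=1e-12)
    assert est.se == pytest.approx(1.0, abs=1e-3)


def test_eap_category_out_of_range(grid, binary_item):
    with pytest.raises(ValueError):
        eap_estimate([(binary_item, 2)], grid)
    with pytest.raises(ValueError):
        eap_estimate([(binary_item, -1)], grid)


@pytest.mark.parametrize("category", [0, 1])
def test_eap_single_binary_item_matches_dense_oracle(grid, dense_grid, binary_item, category):
    est = eap_estimate([(binary_item, category)], grid)
    oracle = eap_estimate([(binary_item, category)], dense_grid)
    assert est.theta == pytest.approx(oracle.theta, abs=1e-6)
    assert est.se == pytest.approx(oracle.se, abs=1e-6)


@pytest.mark.parametrize("seed", range(25))
def test_eap_random_sets_match_dense_oracle(grid, dense_grid, seed):
    """Posterior mean/SD on the 81-node grid vs 10,001-node integration, 1e-6."""
    responses = random_response_set(np.random.default_rng(seed))
    est = eap_estimate(responses, grid)
    oracle = eap_estimate(responses, dense_grid)
    assert est.theta == pytest.approx(oracle.theta, abs=1e-6)
    assert est.se == pytest.approx(oracle.se, abs=1e-6)


def test_eap_mirror_symmetry(grid):
    """On a sign-symmetric bank, mirroring responses flips theta, keeps SE."""
    items = [
        ItemParameters("a", 1.5, (-1.2, -0.4, 0.4, 1.2)),
        ItemParameters("b", 2.0, (-0.9, 0.9)),
        ItemParameters("c", 1.1, (0.0 - 1.5, 0.0, 1.5)),
    ]
    responses = [(items[0], 3), (items[1], 0), (items[2], 1)]
    mirrored = [(it, it.n_categories - 1 - cat) for it, cat in responses]
    est = eap_estimate(responses, grid)
    mir = eap_estimate(mirrored, grid)
    assert mir.theta == pytest.approx(-est.theta, abs=1e-9)
    assert mir.se == pytest.approx(est.se, abs=1e-9)


def test_posterior_variance_martingale(grid, poly_item):
    """Answering an informative item cannot raise posterior variance on average.

    Enumerate the item's categories, weight each posterior variance by its
    prior predictive probability: the mixture never exceeds the prior variance.
    """
    prior_var = eap_estimate([], grid).se ** 2
    probs = category_probabilities(poly_item, grid.nodes)
    predictive = grid.prior_weights @ probs
    assert predictive.sum() == pytest.approx(1.0, abs=1e-12)
    mixed = sum(
        predictive[k] * eap_estimate([(poly_item, k)], grid).se ** 2
        for k in range(poly_item.n_categories)
    )
    assert mixed <= prior_var + 1e-12


def test_quadrature_grid_validation():
    with pytest.raises(ValueError):
        QuadratureGrid(nodes=np.array([0.0, 0.0, 1.0]), prior_weights=np.ones(3))
    with pytest.raises(ValueError):
        QuadratureGrid(nodes=np.array([0.0, 1.0]), prior_weights=np.array([1.0, -1.0]))
    g = QuadratureGrid(nodes=np.array([-1.0, 0.0, 1.0]), prior_weights=np.array([1.0, 2.0, 1.0]))
    assert g.prior_weights.sum() == pytest.approx(1.0, abs=1e-12)
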