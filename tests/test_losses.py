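"""Boundary geometry, loss identities, and differentiability of the composite loss."""

import numpy as np
import pytest

from afnnet import (
    LossWeights,
    aflm_total,
    bce_loss,
    boundary_loss,
    dice_loss,
    distance_map,
    extract_boundary,
    gradient_magnitude,
)
from afnnet.errors import ConfigurationError, ContractViolation
from afnnet.nn import Tensor

from conftest import random_mask
from oracles import bce_ref, boundary_ref, distance_map_ref, gradient_magnitude_ref

SQ2_2 = np.sqrt(2.0) / 2.0


# -- boundary extraction -----------------------------------------------------


def test_boundary_of_empty_mask_is_empty():
    assert extract_boundary(np.zeros((8, 8), dtype=np.uint8)).sum() == 0


def test_boundary_of_single_pixel_is_that_pixel():
    m = np.zeros((5, 5), dtype=np.uint8)
    m[2, 2] = 1
    b = extract_boundary(m)
    assert b[2, 2] == 1 and b.sum() == 1


def test_boundary_of_solid_square_is_its_perimeter():
    m = np.zeros((7, 7), dtype=np.uint8)
    m[2:5, 2:5] = 1
    b = extract_boundary(m)
    expected = m.copy()
    expected[3, 3] = 0  # center is interior
    assert np.array_equal(b, expected)
    assert b.sum() == 8


def test_all_foreground_mask_has_empty_boundary():
    # image-exterior neighbors contribute no label change
    assert extract_boundary(np.ones((6, 6), dtype=np.uint8)).sum() == 0


def test_boundary_matches_enumeration_oracle(rng):
    for _ in range(25):
        m = random_mask(rng, 12, 12)
        assert np.array_equal(extract_boundary(m), boundary_ref(m))


def test_boundary_is_subset_of_foreground(rng):
    m = random_mask(rng, 16, 16)
    b = extract_boundary(m)
    assert (m[b == 1] == 1).all()


def test_boundary_rejects_non_binary():
    with pytest.raises(ContractViolation, match="0 or 1"):
        extract_boundary(np.full((4, 4), 0.5))


# -- distance map ------------------------------------------------------------


def test_distance_map_single_boundary_pixel():
    b = np.zeros((5, 5), dtype=np.uint8)
    b[2, 2] = 1
    d = distance_map(b)
    assert d[2, 2] == 0.0
    assert np.isclose(d[0, 0], 2 * np.sqrt(2.0))


def test_distance_map_empty_boundary_is_zero():
    d = distance_map(np.zeros((6, 6), dtype=np.uint8))
    assert np.array_equal(d, np.zeros((6, 6)))


def test_distance_map_matches_bruteforce_oracle(rng):
    for _ in range(40):
        b = extract_boundary(random_mask(rng, 16, 16))
        assert np.allclose(distance_map(b), distance_map_ref(b), atol=1e-10)


def test_distance_map_translation_equivariance(rng):
    m = np.zeros((20, 20), dtype=np.uint8)
    m[4:9, 5:10] = 1
    d1 = distance_map(extract_boundary(m))
    shifted = np.roll(np.roll(m, 3, axis=0), 2, axis=1)
    d2 = distance_map(extract_boundary(shifted))
    assert np.allclose(np.roll(np.roll(d1, 3, axis=0), 2, axis=1)[8:14, 8:14],
                       d2[8:14, 8:14])


def test_distance_map_normalization_flag():
    b = np.zeros((10, 10), dtype=np.uint8)
    b[5, 5] = 1
    d = distance_map(b, normalize=True)
    assert np.isclose(d.max(), distance_map(b).max() / np.hypot(10, 10))


# -- gradient magnitude ------------------------------------------------------


def test_gradient_magnitude_constant_is_zero():
    assert np.array_equal(gradient_magnitude(np.full((6, 6), 0.7)), np.zeros((6, 6)))


def test_gradient_magnitude_horizontal_ramp():
    W = 8
    p = np.tile(np.arange(W) / (W - 1.0), (5, 1))
    g = gradient_magnitude(p)
    assert np.allclose(g[:, :-1], 1.0 / (W - 1))
    assert np.allclose(g[:, -1], 0.0)  # replicated last column


def test_gradient_magnitude_matches_loop_oracle(rng):
    p = rng.random((6, 6))
    assert np.abs(gradient_magnitude(p) - gradient_magnitude_ref(p)).max() <= 1e-7


@pytest.mark.parametrize("scheme", ["central", "sobel"])
def test_alternative_gradient_schemes_on_ramp(scheme):
    W = 9
    p = np.tile(np.arange(W) / (W - 1.0), (7, 1))
    g = gradient_magnitude(p, scheme=scheme)
    # interior derivative of the ramp is 1/(W-1) for both schemes
    assert np.allclose(g[2:-2, 2:-2], 1.0 / (W - 1), atol=1e-10)


def test_unknown_gradient_scheme_rejected():
    with pytest.raises(ConfigurationError, match="unknown gradient scheme"):
        gradient_magnitude(np.zeros((4, 4)), scheme="upwind")


# -- component losses --------------------------------------------------------


def test_bce_zero_logits_is_ln2(rng):
    G = random_mask(rng, 8, 8)
    assert np.isclose(bce_loss(np.zeros((8, 8)), G).item(), np.log(2.0), atol=1e-9)


def test_bce_saturated_correct_prediction_is_tiny():
    G = np.ones((6, 6), dtype=np.uint8)
    assert bce_loss(np.full((6, 6), 20.0), G).item() <= 1e-8


def test_bce_matches_per_pixel_oracle():
    P = np.array([[0.0, 2.0], [-2.0, 0.0]])
    G = np.array([[0, 1], [1, 0]], dtype=np.uint8)
    assert np.isclose(bce_loss(P, G).item(), bce_ref(P, G), atol=1e-12)


def test_bce_finite_for_extreme_logits(rng):
    G = random_mask(rng, 8, 8)
    v = bce_loss(np.where(G, -1e4, 1e4).astype(float), G).item()
    assert np.isfinite(v)


def test_dice_hard_correct_prediction_is_tiny(rng):
    G = random_mask(rng, 8, 8, p=0.5)
    P = np.where(G, 20.0, -20.0)
    assert dice_loss(P, G, xi=1e-6).item() <= 1e-3


def test_dice_empty_empty_rescued_by_smoothing():
    # saturated-negative logits on an empty mask: xi turns 0/0 into ~0 loss
    G = np.zeros((8, 8), dtype=np.uint8)
    assert dice_loss(np.full((8, 8), -30.0), G, xi=1e-6).item() <= 1e-3


def test_dice_disjoint_halves_is_one():
    G = np.zeros((8, 8), dtype=np.uint8)
    G[:, :4] = 1
    P = np.where(np.arange(8) >= 4, 20.0, -20.0) * np.ones((8, 1))
    assert dice_loss(P, G).item() >= 0.999


def test_dice_requires_positive_smoothing():
    with pytest.raises(ConfigurationError, match="xi"):
        dice_loss(np.zeros((4, 4)), np.zeros((4, 4), dtype=np.uint8), xi=0.0)


def test_boundary_loss_zero_for_constant_logits(rng):
    G = random_mask(rng, 8, 8)
    assert boundary_loss(np.full((8, 8), 3.7), G).item() == 0.0


def test_boundary_loss_zero_for_empty_truth(rng):
    P = rng.normal(size=(8, 8))
    assert boundary_loss(P, np.zeros((8, 8), dtype=np.uint8)).item() == 0.0


def test_boundary_loss_matches_composed_oracles():
    # vertical logit step vs left-half foreground truth, 4x4
    from scipy.special import expit

    P = np.where(np.arange(4) >= 2, 6.0, -6.0) * np.ones((4, 1))
    G = np.zeros((4, 4), dtype=np.uint8)
    G[:, :2] = 1
    expected = (gradient_magnitude_ref(expit(P))
                * distance_map_ref(boundary_ref(G))).mean()
    assert np.isclose(boundary_loss(P, G).item(), expected, atol=1e-12)


def test_boundary_loss_monotone_in_edge_displacement():
    # a sharp sigmoid edge moved k pixels past the true boundary
    H = W = 16
    G = np.zeros((H, W), dtype=np.uint8)
    G[:, :4] = 1
    losses = []
    for k in range(4):
        edge = 4 + k
        P = 12.0 * ((edge - 0.5) - np.arange(W)) * np.ones((H, 1))
        losses.append(boundary_loss(P, G).item())
    assert all(b >= a - 1e-12 for a, b in zip(losses, losses[1:]))
    assert losses[-1] > losses[0]


def test_region_losses_permutation_invariant_boundary_not(rng):
    G = np.zeros((6, 6), dtype=np.uint8)
    G[2:4, 2:4] = 1
    P = rng.normal(size=(6, 6))
    perm = rng.permutation(36)
    P2 = P.ravel()[perm].reshape(6, 6)
    G2 = G.ravel()[perm].reshape(6, 6)
    assert np.isclose(bce_loss(P, G).item(), bce_loss(P2, G2).item(), atol=1e-12)
    assert np.isclose(dice_loss(P, G).item(), dice_loss(P2, G2).item(), atol=1e-12)
    # boundary loss depends on geometry: scrambling changes it
    assert not np.isclose(boundary_loss(P, G).item(), boundary_loss(P2, G2).item(),
                          atol=1e-9)


# -- composite ---------------------------------------------------------------


def test_default_weights_are_the_sqrt2_triple():
    w = LossWeights()
    assert np.isclose(w.alpha, SQ2_2)
    assert np.isclose(w.beta, 1 + SQ2_2)
    assert np.isclose(w.gamma, 1 + SQ2_2)


def test_total_is_weighted_sum_of_components(rng):
    P = rng.normal(size=(2, 1, 8, 8))
    G = (rng.random((2, 1, 8, 8)) < 0.4).astype(np.uint8)
    for w in (LossWeights(), LossWeights(1, 1, 0), LossWeights(1, 0, 1),
              LossWeights(0, 1, 1), LossWeights(0.5, 2, 2)):
        bd = aflm_total(P, G, weights=w)
        expected = (w.alpha * bce_loss(P, G).item()
                    + w.beta * dice_loss(P, G, xi=w.xi).item()
                    + w.gamma * boundary_loss(P, G).item())
        assert abs(bd.total.item() - expected) <= 1e-9


def test_component_scaling_linearity(rng):
    P = rng.normal(size=(1, 1, 8, 8))
    G = (rng.random((1, 1, 8, 8)) < 0.4).astype(np.uint8)
    base = aflm_total(P, G, weights=LossWeights(1, 1, 1))
    scaled = aflm_total(P, G, weights=LossWeights(3, 1, 1))
    assert np.isclose(scaled.total.item() - base.total.item(),
                      2 * base.bce.item(), atol=1e-9)


def test_all_components_nonnegative(rng):
    for _ in range(5):
        P = rng.normal(scale=3.0, size=(1, 1, 10, 10))
        G = (rng.random((1, 1, 10, 10)) < rng.random()).astype(np.uint8)
        bd = aflm_total(P, G)
        assert bd.bce.item() >= 0 and bd.dice.item() >= 0 and bd.boundary.item() >= 0


def test_negative_weights_rejected():
    with pytest.raises(ConfigurationError, match="non-negative"):
        LossWeights(alpha=-0.1)


def test_shape_mismatch_rejected(rng):
    with pytest.raises(ContractViolation, match="differ"):
        bce_loss(np.zeros((4, 4)), np.zeros((5, 4), dtype=np.uint8))


def test_aflm_gradient_matches_finite_differences(rng):
    """Analytic vs central-difference gradient of the total loss, float64 8x8."""
    P0 = rng.normal(size=(1, 1, 8, 8))
    G = (rng.random((1, 1, 8, 8)) < 0.5).astype(np.uint8)
    P = Tensor(P0.copy(), requires_grad=True)
    bd = aflm_total(P, G)
    bd.total.backward()
    eps = 1e-6
    worst = 0.0
    for idx in [(0, 0, 2, 3), (0, 0, 0, 0), (0, 0, 7, 7), (0, 0, 4, 4), (0, 0, 5, 1)]:
        Pp = P0.copy()
        Pp[idx] += eps
        Pm = P0.copy()
        Pm[idx] -= eps
        num = (aflm_total(Pp, G).total.item() - aflm_total(Pm, G).total.item()) / (2 * eps)
        rel = abs(num - P.grad[idx]) / max(abs(num), 1e-8)
        worst = max(worst, rel)
    assert worst < 1e-3
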