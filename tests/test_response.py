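import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neckteeth.response import (COMPOSITE_WEIGHTS, build_composites,
                                composite_gradient, project_reaction_norm,
                                propagate_posterior, respond, response_angle,
                                survival_gradient_template)
from conftest import MODAL_G


def test_survival_templates():
    assert np.array_equal(survival_gradient_template("midge"), [1, -1, 1])
    assert np.array_equal(survival_gradient_template("fish-midge"), [-1, 1, 0])
    # regimes disagree in sign on maximum and sensitivity
    m, f = (survival_gradient_template(r) for r in ("midge", "fish-midge"))
    assert m[0] * f[0] < 0 and m[1] * f[1] < 0
    with pytest.raises(ValueError, match="regime"):
        survival_gradient_template("heron")


def test_composite_orthogonal_inputs():
    g = composite_gradient([1, 0, 0], [0, 1, 0], (1.0, 1.0))
    assert np.allclose(g.vector, [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0])


def test_composite_single_component_is_normalized_input():
    g = composite_gradient([2.0, 0, 0], [0, 1, 0], (1.0, 0.0))
    assert np.allclose(g.vector, [1, 0, 0])


def test_composite_normalizes_reported_reproduction_gradient():
    """The midge reproduction gradient (0.029, 0.016, 0.008) normalizes to
    (0.851, 0.470, 0.235)."""
    g = composite_gradient([0.029, 0.016, 0.008], [1, -1, 1], (1.0, 0.0))
    assert np.allclose(g.vector, [0.851, 0.470, 0.235], atol=1e-3)


def test_composite_cancellation_rejected():
    with pytest.raises(ValueError, match="zero"):
        composite_gradient([1.0, 0, 0], [-1.0, 0, 0], (1.0, 1.0))


def test_five_composites_unit_norm_and_monotone_rotation():
    beta_R = np.array([0.029, 0.016, 0.008])
    grads = build_composites(beta_R, "midge")
    assert [g.label for g in grads] == [lab for lab, _ in COMPOSITE_WEIGHTS]
    bR_hat = beta_R / np.linalg.norm(beta_R)
    angles = []
    for g in grads:
        assert np.linalg.norm(g.vector) == pytest.approx(1.0, abs=1e-12)
        angles.append(response_angle(bR_hat, g.vector))
    # from reproduction-only to survival-only the composite rotates away
    # from the reproduction gradient monotonically
    assert np.all(np.diff(angles) >= -1e-9)
    assert np.allclose(grads[0].vector, bR_hat)
    assert np.allclose(grads[-1].vector, np.array([1, -1, 1]) / np.sqrt(3))


def test_respond_identity_and_diagonal():
    beta = np.array([0.6, -0.64, 0.48])
    total, direct, indirect = respond(np.eye(3), beta)
    assert np.allclose(total, beta) and np.allclose(indirect, 0.0)
    total, direct, indirect = respond(np.diag([0.2, 0.3, 0.4]), beta)
    assert np.allclose(indirect, 0.0)
    with pytest.raises(ValueError, match="dimension"):
        respond(np.eye(2), beta)


def test_respond_modal_G_hand_values():
    """Direct response on the maximum under unit-length midge survival
    selection: G_11 * beta_1 = 0.18 / sqrt(3)."""
    beta = np.array([1.0, -1.0, 1.0]) / np.sqrt(3)
    total, direct, indirect = respond(MODAL_G, beta)
    assert direct[0] == pytest.approx(0.18 * 0.5774, abs=1e-4)
    assert total[0] == pytest.approx(
        (0.18 + 0.12 - 0.001) / np.sqrt(3), abs=1e-12)


@given(st.integers(0, 2 ** 32 - 1))
@settings(max_examples=50, deadline=None)
def test_total_is_direct_plus_indirect(seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    G = A @ A.T
    beta = rng.standard_normal(3)
    total, direct, indirect = respond(G, beta)
    assert np.allclose(total, direct + indirect, atol=1e-12)


@pytest.mark.parametrize("beta, dz, expected", [
    ([1, 0, 0], [1, 0, 0], 0.0),
    ([1, 0, 0], [-1, 0, 0], 180.0),
    ([1, 0, 0], [1, 1, 0], 45.0),
])
def test_response_angle(beta, dz, expected):
    assert response_angle(beta, dz) == pytest.approx(expected)


def test_response_angle_zero_vector_rejected():
    with pytest.raises(ValueError):
        response_angle([0, 0, 0], [1, 0, 0])


def test_propagate_degenerate_posterior():
    draws = np.repeat(np.eye(3)[None], 200, axis=0)
    grad = composite_gradient([1, 0, 0], [0, 1, 0], (1.0, 1.0))
    resp = propagate_posterior(draws, grad)
    assert np.allclose(resp.mode["total"], grad.vector)
    for comp in ("total", "direct", "indirect"):
        width = resp.hpd95[comp][:, 1] - resp.hpd95[comp][:, 0]
        assert np.allclose(width, 0.0)
    assert resp.angle_mode == pytest.approx(0.0)


def test_propagate_monte_carlo_consistency(rng):
    """With draws scattered around a known G, the modal total response is
    within 10% of G_true @ beta."""
    from scipy.stats import wishart

    G_true = np.array([[0.5, 0.35, 0.3], [0.35, 0.5, 0.3], [0.3, 0.3, 0.5]])
    df = 500
    draws = wishart.rvs(df=df, scale=G_true / df, size=10_000, random_state=rng)
    grad = composite_gradient([1.0, 1.0, 0.5], [1, -1, 1], (1.0, 0.0))
    resp = propagate_posterior(draws, grad)
    expected = G_true @ grad.vector
    assert np.all(np.abs(resp.mode["total"] - expected) / np.abs(expected) < 0.10)


def test_significance_flag_matches_independent_hpd(small_draws=None):
    az = pytest.importorskip("arviz")
    rng = np.random.default_rng(0)
    from scipy.stats import wishart
    draws = wishart.rvs(df=30, scale=MODAL_G / 30 + 0.01 * np.eye(3),
                        size=2000, random_state=rng)
    grad = composite_gradient([0.029, 0.016, 0.008], [1, -1, 1], (1.0, 1.0))
    resp = propagate_posterior(draws, grad)
    for comp in ("total", "indirect"):
        arr = resp.draws[comp]
        for k in range(3):
            ref = az.hdi(arr[:, k], hdi_prob=0.95)
            assert resp.significant[comp][k] == bool(ref[0] > 0 or ref[1] < 0)


def test_regime_convergence_under_shared_reproduction_gradient():
    """With the negative maximum-sensitivity covariance, adding a shared
    reproduction gradient pulls the two regimes' responses on the maximum
    toward each other relative to survival-only selection."""
    beta_R = np.array([0.029, 0.016, 0.008])
    responses = {}
    for regime in ("midge", "fish-midge"):
        grads = {g.label: g for g in build_composites(beta_R, regime)}
        responses[regime] = {
            lab: respond(MODAL_G, g.vector)[0][0]   # total on maximum
            for lab, g in grads.items()}
    gap_combined = abs(responses["midge"]["bR+bS"]
                       - responses["fish-midge"]["bR+bS"])
    gap_survival = abs(responses["midge"]["bS"] - responses["fish-midge"]["bS"])
    assert gap_combined < gap_survival


def test_project_reaction_norm_shifts():
    means = {"maximum": 74.0, "sensitivity": 0.13, "reactivity": 0.05}
    record = {"maximum": (74.0, 10.0), "sensitivity": (0.13, 0.1),
              "reactivity": (0.05, 0.02)}
    draws = np.repeat(np.eye(3)[None], 200, axis=0)
    grad = composite_gradient([1, 0, 0], [0, 1, 0], (1.0, 0.0))
    resp = propagate_posterior(draws, grad)     # total = (1, 0, 0)
    out = project_reaction_norm(means, resp, record)
    # +1 standardized unit on the maximum = +1 trait sd in natural units
    assert out["maximum"].iloc[0] == pytest.approx(84.0)
    assert out["sensitivity"].iloc[0] == pytest.approx(0.13)

    # zero response leaves the curve unchanged
    zero = propagate_posterior(np.zeros((200, 3, 3)),
                               composite_gradient([1, 0, 0], [0, 1, 0],
                                                  (1.0, 0.0)))
    out0 = project_reaction_norm(means, zero, record)
    assert np.allclose(out0["projected_induction"], out0["baseline_induction"])

    # a negative shift on sensitivity moves the threshold toward zero
    neg = propagate_posterior(draws, composite_gradient([0, -1, 0], [0, 0, 1],
                                                        (1.0, 0.0)))
    outn = project_reaction_norm(means, neg, record)
    assert outn["sensitivity"].iloc[0] < 0.13
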