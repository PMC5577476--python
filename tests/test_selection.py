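import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from neckteeth.selection import (analyze_pond, canonical_analysis,
                                 fit_selection_surface, fitness_proxy,
                                 randomization_test)

COLS = ["maximum", "sensitivity", "reactivity"]


def frame(Z):
    return pd.DataFrame(Z, columns=COLS)


@pytest.mark.parametrize("age, clutch, expected", [
    (10.0, 10, 0.0),
    (5.0, 10, np.log(2.0)),
])
def test_fitness_proxy_values(age, clutch, expected):
    assert fitness_proxy(age, clutch) == pytest.approx(expected)


def test_fitness_proxy_monotone_and_guarded():
    assert fitness_proxy(5.0, 8) > fitness_proxy(10.0, 8)
    assert fitness_proxy(10.0, 12) > fitness_proxy(10.0, 8)
    with pytest.raises(ValueError):
        fitness_proxy(0.0, 5)
    with pytest.raises(ValueError):
        fitness_proxy(5.0, 0)


def test_exact_linear_surface(rng):
    Z = rng.standard_normal((36, 3))
    s = fit_selection_surface(frame(Z), 1.0 + 0.3 * Z[:, 0])
    assert np.allclose(s.beta, [0.3, 0.0, 0.0], atol=1e-10)
    assert np.allclose(s.gamma, 0.0, atol=1e-10)


def test_pure_quadratic_doubling(rng):
    Z = rng.standard_normal((36, 3))
    s = fit_selection_surface(frame(Z), Z[:, 0] ** 2)
    assert s.gamma[0, 0] == pytest.approx(2.0, abs=1e-10)
    assert s.gamma_raw[0, 0] == pytest.approx(1.0, abs=1e-10)


def test_constant_fitness_gives_null_surface(rng):
    Z = rng.standard_normal((36, 3))
    s = fit_selection_surface(frame(Z), np.full(36, 1.7))
    assert np.allclose(s.beta, 0.0, atol=1e-12)
    assert np.allclose(s.gamma, 0.0, atol=1e-12)


def test_intercept_shift_equivariance(rng):
    Z = rng.standard_normal((36, 3))
    w = rng.standard_normal(36)
    s1 = fit_selection_surface(frame(Z), w)
    s2 = fit_selection_surface(frame(Z), w + 5.0)
    assert np.allclose(s1.beta, s2.beta)
    assert np.allclose(s1.gamma, s2.gamma)


def test_rank_deficiency_names_columns(rng):
    Z = rng.standard_normal((36, 3))
    Z[:, 2] = Z[:, 1]
    with pytest.raises(ValueError, match="reactivity"):
        fit_selection_surface(frame(Z), rng.standard_normal(36))


def test_permutation_floor_and_power(rng):
    Z = rng.standard_normal((36, 3))
    w = 1.0 * Z[:, 0] + rng.normal(0, 0.1, 36)
    s = fit_selection_surface(frame(Z), w)
    s = randomization_test(frame(Z), w, s, B=200, seed=0)
    floor = 1.0 / 201.0
    assert np.all(s.p_beta >= floor - 1e-12)
    assert np.all(s.p_gamma >= floor - 1e-12)
    assert s.p_beta[0] == pytest.approx(floor)


def test_permutation_requires_enough_draws(rng):
    Z = rng.standard_normal((36, 3))
    w = rng.standard_normal(36)
    s = fit_selection_surface(frame(Z), w)
    with pytest.raises(ValueError):
        randomization_test(frame(Z), w, s, B=50, seed=0)


def test_null_pvalues_uniform():
    """Under no selection, permutation p-values are uniform on their grid."""
    master = np.random.default_rng(7)
    pvals = []
    for _ in range(1000):
        Z = master.standard_normal((36, 3))
        w = master.standard_normal(36)
        s = fit_selection_surface(frame(Z), w)
        s = randomization_test(frame(Z), w, s, B=200,
                               seed=int(master.integers(2 ** 31)))
        pvals.append(s.p_beta[0])
    stat = kstest(pvals, "uniform")
    assert stat.pvalue > 0.01


def test_canonical_diagonal_case():
    lam, M = canonical_analysis(np.diag([2.0, -1.0, 0.5]))
    assert np.allclose(lam, [2.0, 0.5, -1.0])
    # signed permutation of the identity
    assert np.allclose(np.abs(M), np.eye(3)[:, [0, 2, 1]])


def test_canonical_two_by_two_toy():
    gamma = np.zeros((3, 3))
    gamma[0, 1] = gamma[1, 0] = 1.0
    lam, M = canonical_analysis(gamma)
    assert np.allclose(sorted(lam), [-1.0, 0.0, 1.0])
    v = M[:, 0]
    assert np.allclose(np.abs(v[:2]), 1 / np.sqrt(2)) and v[2] == pytest.approx(0.0)


def test_canonical_identities(rng):
    A = rng.standard_normal((3, 3))
    gamma = A + A.T
    lam, M = canonical_analysis(gamma)
    assert np.allclose(M.T @ M, np.eye(3), atol=1e-10)
    assert np.allclose(M @ np.diag(lam) @ M.T, gamma, atol=1e-10)
    assert np.trace(gamma) == pytest.approx(lam.sum())


def test_canonical_rejects_asymmetric():
    with pytest.raises(ValueError, match="symmetric"):
        canonical_analysis(np.array([[0.0, 1.0, 0], [0, 0, 0], [0, 0, 0]]))


def test_saddle_classification(rng):
    Z = rng.standard_normal((40, 3))
    w = Z[:, 0] ** 2 - Z[:, 1] ** 2 + rng.normal(0, 0.1, 40)
    s = fit_selection_surface(frame(Z), w)
    s = randomization_test(frame(Z), w, s, B=199, seed=1)
    assert s.surface_shape == "saddle"


def test_analyze_pond_end_to_end(default_traits, default_dataset):
    _, traits = default_traits
    _, _, lifehistory, truth = default_dataset
    s = analyze_pond(traits, lifehistory, "midge", B=499, seed=3)
    assert s.n == 21            # 7 midge clones x 3 mothers
    assert s.beta.shape == (3,)
    assert s.p_beta.shape == (3,) and np.all((s.p_beta > 0) & (s.p_beta <= 1))
    assert np.allclose(s.M @ np.diag(s.lambdas) @ s.M.T, s.gamma, atol=1e-10)
    assert s.meta["pond"] == "midge"
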