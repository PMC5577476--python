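import numpy as np
import pandas as pd
import pytest

from neckteeth import fitness_proxy
from neckteeth.simulate import (SimulationConfig, generate_dataset,
                                invert_fitness, simulate_trait_table)


def test_default_design_bookkeeping(default_dataset):
    cfg, induction, lifehistory, truth = default_dataset
    # 15 neonates per genotype per concentration: 3 mothers x 5 replicates
    per_cell = (induction.drop_duplicates("individual")
                .groupby(["clone", "concentration"])["individual"].count())
    assert (per_cell == 15).all()
    assert induction["concentration"].nunique() == 7
    assert induction["individual"].nunique() == 12 * 3 * 5 * 7 == 1260
    assert len(lifehistory) == 1260
    assert set(induction["pond"]) == {"midge", "fish-midge"}
    assert (pd.Series(list(truth.line_traits)).size == 36)


def test_seed_determinism():
    a = generate_dataset(SimulationConfig(seed=31))
    b = generate_dataset(SimulationConfig(seed=31))
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    assert a[2].to_json() == b[2].to_json()
    c = generate_dataset(SimulationConfig(seed=32))
    assert not a[0].equals(c[0])


def test_zero_variance_sources_give_identical_lines():
    cfg = SimulationConfig(G_true=np.zeros((3, 3)), maternal_var=(0, 0, 0),
                           residual_sd_induction=0.0, fitness_noise_sd=0.0,
                           seed=1)
    _, _, truth = generate_dataset(cfg)
    traits = np.array(list(truth.line_traits.values())).reshape(12, 3, 3)
    ponds = cfg.pond_assignment
    for ci in range(12):
        ref = truth.line_traits[(f"c{1:02d}" if ponds[ci] == "midge"
                                 else "c08"), "m1"]
        assert np.allclose(traits[ci], ref)


def test_non_psd_G_rejected_with_eigenvalue():
    bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(ValueError, match="eigenvalue"):
        SimulationConfig(G_true=bad)


def test_invalid_counts_and_concentrations_rejected():
    with pytest.raises(ValueError, match=">= 1"):
        SimulationConfig(n_mothers_per_clone=0)
    with pytest.raises(ValueError, match="concentrations"):
        SimulationConfig(concentrations=(0.1, 0.25, 0.5))
    with pytest.raises(ValueError, match="concentrations"):
        SimulationConfig(concentrations=(0.0, 0.5, 0.25))


def test_extended_clone_gets_extra_doses():
    cfg = SimulationConfig(extended_clone="c01", seed=2)
    induction, _, _ = generate_dataset(cfg)
    assert induction.loc[induction["clone"] == "c01", "concentration"].nunique() == 11
    assert induction.loc[induction["clone"] == "c02", "concentration"].nunique() == 7


@pytest.mark.parametrize("w, ages, expected", [
    (0.0, [10.0], (10.0, 10)),
    (np.log(2.0), [5.0], (5.0, 10)),
])
def test_invert_fitness_examples(w, ages, expected):
    assert invert_fitness(w, ages) == expected


def test_invert_fitness_unreachable_flagged():
    with pytest.raises(ValueError, match="unreachable"):
        invert_fitness(-8.0, [5.0, 10.0])


def test_invert_fitness_round_trip(rng):
    """proxy(invert_fitness(w)) == w up to clutch rounding, 1000 draws."""
    grid = np.arange(5.0, 15.01, 0.5)
    for w in rng.uniform(-1.0, 1.5, 1000):
        age, clutch = invert_fitness(w, grid, rng=rng)
        w_back = fitness_proxy(age, clutch)
        # rounding the clutch perturbs w by at most ln(c / (c - 0.5))
        assert abs(w_back - w) <= np.log(clutch / (clutch - 0.5)) + 1e-12


def test_clone_covariance_converges_to_G_true():
    """Empirical covariance of the clone deviates approaches G_true."""
    G = np.array([[0.5, 0.35, 0.3], [0.35, 0.5, 0.3], [0.3, 0.3, 0.5]])
    cfg = SimulationConfig(
        n_clones=500, pond_assignment=tuple(["midge"] * 250 + ["fish-midge"] * 250),
        n_mothers_per_clone=1, n_reps_per_mother_per_conc=1,
        concentrations=(0.0, 0.1, 0.25, 0.5), G_true=G, seed=4)
    _, _, truth = generate_dataset(cfg)
    dev = np.array(list(truth.clone_deviates.values()))
    emp = np.cov(dev.T)
    assert np.all(np.abs(emp - G) / np.abs(G) < 0.15)


def test_induction_levels_truncated(default_dataset, default_traits):
    scored, _ = default_traits
    assert scored["induction"].between(0.0, 100.0).all()


def test_lifehistory_encodes_true_fitness(default_dataset):
    """Mean per-line proxy recovers the true line fitness up to noise."""
    cfg, _, lifehistory, truth = default_dataset
    lh = lifehistory.copy()
    lh["w"] = fitness_proxy(lh["age_first_repro"], lh["clutch_size"])
    per_line = lh.groupby(["clone", "mother"])["w"].mean()
    true_w = pd.Series(truth.line_fitness)
    resid = (per_line - true_w).to_numpy()
    # per-line mean of 35 noisy replicates, sd 0.1 -> SE ~ 0.017 plus rounding
    assert np.abs(resid).max() < 0.1
    assert abs(resid.mean()) < 0.02


def test_simulate_trait_table_structure():
    tab = simulate_trait_table(10, 3, np.eye(3) * 0.3, 0.5 * np.eye(3), seed=0)
    assert len(tab) == 30
    assert tab["clone"].nunique() == 10
    assert set(tab.columns) >= {"clone", "pond", "mother", "maximum",
                                "sensitivity", "reactivity"}
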