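"""Synthetic clonal induction experiments with known ground truth.

The generator emulates the structure of a clonal *Daphnia pulex*
kairomone-gradient experiment: iso-female clones from two source ponds
(one with midge predators only, one with fish and midge), three mothers
per clone, and a fixed number of neonates per mother at each cue
concentration along a seven-point gradient. Each maternal line carries a
true trait triple (maximum, sensitivity, reactivity) built as

    pond mean + trait_sd * (clone deviate + maternal deviate)

where clone deviates are drawn from the true clone-level covariance
``G_true`` and maternal deviates from a diagonal maternal-effect
covariance, both on the standardized-trait scale. Individual induction at
dose x is the line's sigmoid plus Gaussian score noise, truncated to
[0, 100], and is emitted as per-instar pedestal/spike observations that
score back to the intended induction level. Life-history rows (age at
first reproduction, first clutch size) are constructed so that the log
quotient fitness proxy recovers a true selection surface
w = intercept + beta' z + z' gamma z / 2 evaluated at the line's
standardized deviate z.

Every random stream is split deterministically from the master seed, so a
given configuration reproduces its tables exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .scoring import PEDESTAL_POINTS, REFERENCE_MAX_SCORE, SPIKE_POINTS
from .sigmoid import three_param_logistic

TRAITS = ("maximum", "sensitivity", "reactivity")

#: Clone-level covariance used by default (standardized-trait scale): a
#: modest variance in the maximum, a larger one in sensitivity, little in
#: reactivity, and a negative maximum-sensitivity covariance.
DEFAULT_G_TRUE = np.array([
    [0.18, -0.12, -0.001],
    [-0.12, 0.35, 0.03],
    [-0.001, 0.03, 0.02],
])

#: True reproduction-selection surface (standardized-trait scale); the
#: gamma diagonal follows the doubled-coefficient convention.
DEFAULT_BETA_TRUE = np.array([0.029, 0.016, 0.008])
DEFAULT_GAMMA_TRUE = np.array([
    [0.189, -0.175, 0.087],
    [-0.175, 0.095, -0.225],
    [0.087, -0.225, 0.096],
])

DEFAULT_CONCENTRATIONS = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0, 2.0)
EXTENDED_CONCENTRATIONS = (0.15, 0.4, 0.6, 0.8)


def _default_ponds():
    return tuple(["midge"] * 7 + ["fish-midge"] * 5)


@dataclass
class SimulationConfig:
    """Design and ground truth of one synthetic clonal experiment.

    Defaults reproduce the reference design: 12 clones (7 from the midge
    pond, 5 from the fish-midge pond), 3 mothers per clone, 5 neonates per
    mother per concentration on the 7-point gradient, pond trait means of
    (74, 0.13, 0.05) and (55, 0.42, 0.08) in natural units (induction
    0-100, ul/ml, ul/ml).
    """

    n_clones: int = 12
    pond_assignment: tuple = field(default_factory=_default_ponds)
    n_mothers_per_clone: int = 3
    n_reps_per_mother_per_conc: int = 5
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    extended_clone: str | None = None
    extended_concentrations: tuple = EXTENDED_CONCENTRATIONS
    pond_trait_means: dict = field(default_factory=lambda: {
        "midge": (74.0, 0.13, 0.05),
        "fish-midge": (55.0, 0.42, 0.08),
    })
    trait_sd: tuple = (10.0, 0.10, 0.02)
    G_true: np.ndarray = field(default_factory=lambda: DEFAULT_G_TRUE.copy())
    maternal_var: tuple = (0.05, 0.05, 0.05)
    residual_sd_induction: float = 8.0
    beta_true: np.ndarray = field(default_factory=lambda: DEFAULT_BETA_TRUE.copy())
    gamma_true: np.ndarray = field(default_factory=lambda: DEFAULT_GAMMA_TRUE.copy())
    fitness_intercept: float = 0.0
    fitness_noise_sd: float = 0.1
    age_grid: tuple = tuple(np.arange(5.0, 15.01, 0.5))
    seed: int = 0

    def __post_init__(self):
        self.G_true = np.asarray(self.G_true, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.validate()

    def validate(self):
        if self.n_clones < 1 or self.n_mothers_per_clone < 1 \
                or self.n_reps_per_mother_per_conc < 1:
            raise ValueError("clone, mother and replicate counts must be >= 1")
        if len(self.pond_assignment) != self.n_clones:
            raise ValueError("pond_assignment length must equal n_clones")
        conc = np.asarray(self.concentrations, dtype=float)
        if conc[0] != 0.0 or np.any(np.diff(conc) <= 0) or np.any(conc < 0):
            raise ValueError("concentrations must be non-negative, strictly "
                             "increasing and include 0")
        if not np.allclose(self.G_true, self.G_true.T):
            raise ValueError("G_true must be symmetric")
        eig = np.linalg.eigvalsh(self.G_true)
        if eig.min() < -1e-10:
            raise ValueError(f"G_true is not positive semidefinite: "
                             f"eigenvalue {eig.min():.3g} < 0")
        for pond, means in self.pond_trait_means.items():
            mx, sens, scale = means
            if not (0.0 <= mx <= 100.0):
                raise ValueError(f"pond {pond!r}: maximum {mx} outside [0, 100]")
            if sens <= 0 or scale <= 0:
                raise ValueError(f"pond {pond!r}: inflection and scale must be > 0")
        if not np.allclose(self.gamma_true, self.gamma_true.T):
            raise ValueError("gamma_true must be symmetric")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("pond_assignment", "concentrations", "extended_concentrations",
                    "maternal_var", "trait_sd", "age_grid"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("G_true", "beta_true", "gamma_true"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("G_true", "beta_true", "gamma_true"):
            d[key] = np.asarray(d[key]).tolist()
        return d


@dataclass
class TruthRecord:
    """Ground truth behind one synthetic dataset."""

    config: dict
    clone_deviates: dict              # clone -> standardized 3-vector
    line_deviates: dict               # (clone, mother) -> standardized 3-vector
    line_traits: dict                 # (clone, mother) -> natural-unit 3-vector
    line_fitness: dict                # (clone, mother) -> true w
    G_true: list
    beta_true: list
    gamma_true: list

    def to_json(self) -> str:
        def keyfix(d):
            return {"|".join(k) if isinstance(k, tuple) else k:
                    (np.asarray(v).tolist() if not np.isscalar(v) else v)
                    for k, v in d.items()}
        payload = {
            "config": self.config,
            "clone_deviates": keyfix(self.clone_deviates),
            "line_deviates": keyfix(self.line_deviates),
            "line_traits": keyfix(self.line_traits),
            "line_fitness": keyfix(self.line_fitness),
            "G_true": self.G_true,
            "beta_true": self.beta_true,
            "gamma_true": self.gamma_true,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# fitness inversion

def invert_fitness(target_w: float, age_grid, rng=None):
    """Turn a target fitness proxy into an (age, clutch) pair.

    w = ln(clutch / age) implies clutch = age * exp(w); the clutch is
    rounded to an integer, so the recovered proxy matches ``target_w`` up
    to that rounding. With an ``rng``, the age is drawn uniformly from the
    feasible grid ages; otherwise the age minimizing the clutch rounding
    error is chosen (ties to the smallest age).
    """
    ages = np.atleast_1d(np.asarray(age_grid, dtype=float))
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    clutch_real = ages * np.exp(target_w)
    feasible = clutch_real >= 0.5          # rounds to >= 1
    if not feasible.any():
        raise ValueError(
            f"target fitness {target_w:.4g} unreachable with clutch >= 1 "
            "on the supplied age grid")
    ages_f = ages[feasible]
    clutch_f = clutch_real[feasible]
    if rng is not None:
        i = int(rng.integers(ages_f.size))
    else:
        err = np.abs(clutch_f - np.round(clutch_f))
        i = int(np.argmin(err))            # argmin ties -> first (smallest age)
    return float(ages_f[i]), int(np.round(clutch_f[i]))


# ---------------------------------------------------------------------------
# pedestal / spike synthesis

def _raw_to_pedestal_spikes(raw: int):
    """Decompose a raw score (multiple of 10, <= 130) into a pedestal class
    and spike count under the scoring rule."""
    if raw >= PEDESTAL_POINTS["large"]:
        return "large", (raw - PEDESTAL_POINTS["large"]) // SPIKE_POINTS
    if raw >= PEDESTAL_POINTS["small"]:
        return "small", (raw - PEDESTAL_POINTS["small"]) // SPIKE_POINTS
    return "absent", raw // SPIKE_POINTS


def _induction_to_raw(induction: float) -> int:
    """Nearest achievable raw score for an induction level in [0, 100]."""
    raw = induction / 100.0 * REFERENCE_MAX_SCORE
    return int(np.clip(np.round(raw / SPIKE_POINTS) * SPIKE_POINTS,
                       0, REFERENCE_MAX_SCORE))


# ---------------------------------------------------------------------------
# the generator

def generate_dataset(config: SimulationConfig):
    """Simulate one clonal experiment.

    Returns ``(induction, lifehistory, truth)``: a per-instar induction
    table, a per-individual life-history table, and the
    :class:`TruthRecord` holding the deviates, traits and fitness values
    actually used.
    """
    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_traits, rng_induction, rng_life = [
        np.random.default_rng(s) for s in ss.spawn(3)]

    clones = [f"c{j + 1:02d}" for j in range(cfg.n_clones)]
    mothers = [f"m{j + 1}" for j in range(cfg.n_mothers_per_clone)]
    trait_sd = np.asarray(cfg.trait_sd, dtype=float)

    # clone and maternal deviates on the standardized scale
    eigval, eigvec = np.linalg.eigh(cfg.G_true)
    L = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    clone_dev = rng_traits.standard_normal((cfg.n_clones, 3)) @ L.T
    mat_sd = np.sqrt(np.asarray(cfg.maternal_var, dtype=float))
    mother_dev = rng_traits.standard_normal(
        (cfg.n_clones, cfg.n_mothers_per_clone, 3)) * mat_sd

    clone_deviates = {}
    line_deviates = {}
    line_traits = {}
    line_fitness = {}

    induction_rows = []
    life_rows = []
    age_grid = np.asarray(cfg.age_grid, dtype=float)
    gamma = cfg.gamma_true

    for ci, clone in enumerate(clones):
        pond = cfg.pond_assignment[ci]
        means = np.asarray(cfg.pond_trait_means[pond], dtype=float)
        clone_deviates[clone] = clone_dev[ci]
        doses = list(cfg.concentrations)
        if cfg.extended_clone == clone:
            doses = sorted(doses + list(cfg.extended_concentrations))
        for mi, mother in enumerate(mothers):
            z = clone_dev[ci] + mother_dev[ci, mi]
            traits = means + trait_sd * z
            # inflection and scale must stay strictly positive
            traits[1] = max(traits[1], 1e-3)
            traits[2] = max(traits[2], 1e-3)
            line_deviates[(clone, mother)] = z
            line_traits[(clone, mother)] = traits
            w_line = (cfg.fitness_intercept + cfg.beta_true @ z
                      + 0.5 * z @ gamma @ z)
            line_fitness[(clone, mother)] = float(w_line)

            indiv_counter = 0
            for dose in doses:
                mean_induction = three_param_logistic(dose, *traits)
                for _ in range(cfg.n_reps_per_mother_per_conc):
                    indiv_counter += 1
                    individual = f"{clone}-{mother}-x{dose:g}-{indiv_counter}"
                    target = float(np.clip(
                        mean_induction
                        + rng_induction.normal(0.0, cfg.residual_sd_induction),
                        0.0, 100.0))
                    raw_main = _induction_to_raw(target)
                    # strongest expression in the 2nd instar; weaker neighbours
                    fracs = rng_induction.uniform(0.2, 0.8, size=2)
                    for instar, raw in (
                            (1, min(raw_main, _induction_to_raw(
                                target * fracs[0]))),
                            (2, raw_main),
                            (3, min(raw_main, _induction_to_raw(
                                target * fracs[1])))):
                        ped, spikes = _raw_to_pedestal_spikes(int(raw))
                        induction_rows.append({
                            "clone": clone, "pond": pond, "mother": mother,
                            "individual": individual, "instar": instar,
                            "concentration": dose, "pedestal": ped,
                            "spikes": int(spikes),
                        })
                    w_i = w_line + rng_life.normal(0.0, cfg.fitness_noise_sd)
                    age, clutch = invert_fitness(w_i, age_grid, rng=rng_life)
                    life_rows.append({
                        "clone": clone, "pond": pond, "mother": mother,
                        "individual": individual,
                        "age_first_repro": age, "clutch_size": clutch,
                    })

    induction = pd.DataFrame(induction_rows)
    lifehistory = pd.DataFrame(life_rows)
    truth = TruthRecord(
        config=cfg.to_dict(),
        clone_deviates=clone_deviates,
        line_deviates=line_deviates,
        line_traits=line_traits,
        line_fitness=line_fitness,
        G_true=cfg.G_true.tolist(),
        beta_true=cfg.beta_true.tolist(),
        gamma_true=cfg.gamma_true.tolist(),
    )
    return induction, lifehistory, truth


def simulate_trait_table(n_clones: int, n_mothers: int, G: np.ndarray,
                         R: np.ndarray, seed: int | None = None,
                         pond_split: float = 0.5,
                         pond_shift: np.ndarray | None = None) -> pd.DataFrame:
    """Directly simulate a standardized TraitTable from the mixed model
    y = pond effect + clone deviate + residual.

    A lightweight generator for studying the G-matrix sampler on its own,
    bypassing the induction/fitting stages.
    """
    rng = np.random.default_rng(seed)
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    eigval, eigvec = np.linalg.eigh(G)
    Lg = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    Lr = np.linalg.cholesky(R)
    n_midge = int(round(pond_split * n_clones))
    shift = np.zeros(3) if pond_shift is None else np.asarray(pond_shift, float)
    rows = []
    for ci in range(n_clones):
        pond = "midge" if ci < n_midge else "fish-midge"
        u = Lg @ rng.standard_normal(3)
        for mi in range(n_mothers):
            e = Lr @ rng.standard_normal(3)
            y = (shift if pond == "midge" else -shift) + u + e
            rows.append({"clone": f"c{ci + 1:02d}", "pond": pond,
                         "mother": f"m{mi + 1}",
                         "maximum": y[0], "sensitivity": y[1],
                         "reactivity": y[2]})
    return pd.DataFrame(rows)
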