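"""Multivariate response to selection for the reaction norm.

Composite selection gradients mix an estimated reproduction gradient
(beta_R, from the selection analysis) with a hypothetical survival gradient
(beta_S, a sign template from size-selective predation theory: midge
larvae take small prey and favour stronger, more sensitive, faster
induction; fish take large prey and disfavour the defence). Each input and
each composite is standardized to unit Euclidean length so that the
composites differ in direction, not strength.

The per-generation response is the multivariate breeder's equation
Delta z = G beta, decomposed per trait into the direct part through the
trait's own genetic variance (G_ii beta_i) and the indirect part through
genetic covariances (sum_{j != i} G_ij beta_j). Propagating the G
posterior through the equation yields posterior modes and 95% HPD
intervals for every component. Responses are on the standardized trait
scale; back-transformation is only applied when projecting shifted
reaction-norm curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmatrix import GMatrixPosterior, hpd_interval, posterior_mode
from .sigmoid import three_param_logistic

TRAITS = ("maximum", "sensitivity", "reactivity")

#: The five reproduction/survival weightings, from reproduction-only to
#: survival-only.
COMPOSITE_WEIGHTS = (
    ("bR", (1.0, 0.0)),
    ("bR+0.5bS", (1.0, 0.5)),
    ("bR+bS", (1.0, 1.0)),
    ("0.5bR+bS", (0.5, 1.0)),
    ("bS", (0.0, 1.0)),
)

_SURVIVAL_TEMPLATES = {
    # (maximum, sensitivity, reactivity) sign structure
    "midge": np.array([1.0, -1.0, 1.0]),
    "fish-midge": np.array([-1.0, 1.0, 0.0]),
}


def survival_gradient_template(regime: str) -> np.ndarray:
    """Hypothetical survival gradient for a predation regime.

    midge: survival improves with a higher maximum, a lower (more
    sensitive) threshold and faster induction -> (+1, -1, +1).
    fish-midge: the defence is not favoured -> (-1, +1, 0), with no
    survival selection on reactivity.
    """
    key = regime.replace("–", "-").replace("_", "-").lower()
    if key not in _SURVIVAL_TEMPLATES:
        raise ValueError(f"unknown predation regime {regime!r}; "
                         f"expected one of {sorted(_SURVIVAL_TEMPLATES)}")
    return _SURVIVAL_TEMPLATES[key].copy()


@dataclass
class CompositeGradient:
    """A unit-length weighted combination of reproduction and survival
    selection."""

    label: str
    regime: str
    vector: np.ndarray
    weights: tuple = (1.0, 0.0)


def composite_gradient(beta_R, beta_S, weights, label: str = "",
                       regime: str = "") -> CompositeGradient:
    """Form w_R * unit(beta_R) + w_S * unit(beta_S), renormalized to
    unit length."""
    bR = np.asarray(beta_R, dtype=float)
    bS = np.asarray(beta_S, dtype=float)
    w_R, w_S = weights
    nR, nS = np.linalg.norm(bR), np.linalg.norm(bS)
    if w_R != 0 and nR == 0:
        raise ValueError("beta_R is a zero vector")
    if w_S != 0 and nS == 0:
        raise ValueError("beta_S is a zero vector")
    vec = np.zeros(3)
    if w_R != 0:
        vec = vec + w_R * bR / nR
    if w_S != 0:
        vec = vec + w_S * bS / nS
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise ValueError(
            f"composite gradient cancels to zero for weights {weights}; "
            "the reproduction and survival gradients are antiparallel")
    return CompositeGradient(label or f"{w_R}bR+{w_S}bS", regime, vec / norm,
                             (w_R, w_S))


def build_composites(beta_R, regime: str) -> list[CompositeGradient]:
    """The five standard composites for one predation regime."""
    beta_S = survival_gradient_template(regime)
    return [composite_gradient(beta_R, beta_S, w, label=lab, regime=regime)
            for lab, w in COMPOSITE_WEIGHTS]


def respond(G: np.ndarray, beta: np.ndarray):
    """One-generation breeder's-equation response for a single G.

    Returns (total, direct, indirect) per trait with
    total_i = sum_j G_ij beta_j, direct_i = G_ii beta_i,
    indirect_i = total_i - direct_i (computed as the off-diagonal sum).
    """
    G = np.asarray(G, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if G.shape != (beta.size, beta.size):
        raise ValueError(f"dimension mismatch: G {G.shape}, beta {beta.shape}")
    total = G @ beta
    direct = np.diag(G) * beta
    indirect = total - direct
    return total, direct, indirect


def response_angle(beta, delta_z) -> float:
    """Angle in degrees between the selection gradient and the response."""
    b = np.asarray(beta, dtype=float)
    d = np.asarray(delta_z, dtype=float)
    nb, nd = np.linalg.norm(b), np.linalg.norm(d)
    if nb == 0 or nd == 0:
        raise ValueError("cannot measure the angle to a zero vector")
    c = np.clip(b @ d / (nb * nd), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class SelectionResponse:
    """Posterior summary of Delta z for one composite gradient."""

    label: str
    regime: str
    beta: np.ndarray
    draws: dict                       # {"total"|"direct"|"indirect": (d, 3)}
    mode: dict                        # {component: (3,)}
    hpd95: dict                       # {component: (3, 2)}
    significant: dict                 # {component: bool (3,)} HPD excludes 0
    angle_mode: float
    angle_hpd95: tuple
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in ("total", "direct", "indirect"):
            for k, trait in enumerate(TRAITS):
                rows.append({
                    "regime": self.regime, "composite": self.label,
                    "trait": trait, "component": comp,
                    "mode": self.mode[comp][k],
                    "hpd_lo": self.hpd95[comp][k, 0],
                    "hpd_hi": self.hpd95[comp][k, 1],
                    "significant": bool(self.significant[comp][k]),
                    "angle_mode": self.angle_mode,
                })
        return pd.DataFrame(rows)


def propagate_posterior(posterior: GMatrixPosterior | np.ndarray,
                        gradient: CompositeGradient) -> SelectionResponse:
    """Apply the breeder's equation to every posterior G draw and summarize.

    Accepts a :class:`GMatrixPosterior` or a raw (d, 3, 3) array of draws.
    """
    G_draws = posterior.G_draws if hasattr(posterior, "G_draws") else np.asarray(posterior)
    d = G_draws.shape[0]
    if d < 100:
        import warnings
        warnings.warn(f"only {d} G draws; response intervals will be noisy",
                      stacklevel=2)
    beta = gradient.vector
    total = np.einsum("dij,j->di", G_draws, beta)
    direct = np.einsum("dii->di", G_draws) * beta
    indirect = total - direct
    draws = {"total": total, "direct": direct, "indirect": indirect}

    mode, hpd, sig = {}, {}, {}
    for comp, arr in draws.items():
        mode[comp] = np.array([posterior_mode(arr[:, k]) for k in range(3)])
        hpd[comp] = np.array([hpd_interval(arr[:, k]) for k in range(3)])
        sig[comp] = (hpd[comp][:, 0] > 0) | (hpd[comp][:, 1] < 0)

    angles = np.array([response_angle(beta, total[i]) for i in range(d)
                       if np.linalg.norm(total[i]) > 0])
    angle_mode = posterior_mode(angles) if angles.size else float("nan")
    angle_hpd = hpd_interval(angles) if angles.size else (float("nan"),) * 2
    return SelectionResponse(gradient.label, gradient.regime, beta, draws,
                             mode, hpd, sig, angle_mode, angle_hpd)


def project_reaction_norm(pond_means: dict, response: SelectionResponse,
                          standardization: dict,
                          dose_grid=None) -> pd.DataFrame:
    """Shift the pond-mean reaction norm by the modal total response.

    The modal Delta z (standardized scale) is added to the standardized pond
    means, back-transformed to natural units (clipping the maximum to
    [0, 100] and keeping sensitivity/reactivity positive), and the implied
    sigmoid evaluated on a dose grid.
    """
    import warnings

    if dose_grid is None:
        dose_grid = np.linspace(0.0, 2.0, 101)
    dose_grid = np.asarray(dose_grid, dtype=float)

    shifted = {}
    for k, trait in enumerate(TRAITS):
        mu, sd = standardization[trait]
        z0 = (pond_means[trait] - mu) / sd
        shifted[trait] = (z0 + response.mode["total"][k]) * sd + mu
    shifted["maximum"] = float(np.clip(shifted["maximum"], 0.0, 100.0))
    for trait in ("sensitivity", "reactivity"):
        if shifted[trait] <= 0:
            warnings.warn(f"projected {trait} non-positive; clipped to 1e-4",
                          stacklevel=2)
            shifted[trait] = 1e-4

    baseline = three_param_logistic(dose_grid, pond_means["maximum"],
                                    pond_means["sensitivity"],
                                    pond_means["reactivity"])
    projected = three_param_logistic(dose_grid, shifted["maximum"],
                                     shifted["sensitivity"],
                                     shifted["reactivity"])
    return pd.DataFrame({
        "concentration": dose_grid,
        "baseline_induction": baseline,
        "projected_induction": projected,
        "regime": response.regime,
        "composite": response.label,
        "maximum": shifted["maximum"],
        "sensitivity": shifted["sensitivity"],
        "reactivity": shifted["reactivity"],
    })
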