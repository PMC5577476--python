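"""Selection gradients on the reaction-norm traits.

Fitness is proxied by the log quotient of first clutch size over age at
first reproduction, w = ln(clutch / age), which increases with fecundity
and with earlier maturation and is closely tied to population growth rate
in an expanding population. The proxy is used unrelativized: every
composite gradient built from it downstream is rescaled to unit length, so
positive scalings of w cancel.

Directional gradients (beta) come from the first-order least-squares
regression of w on the three standardized traits; quadratic and
correlational gradients (gamma) from the full second-order regression,
with the fitted quadratic coefficients doubled on the diagonal so they
estimate the curvature of the fitness surface without the factor-of-two
bias. Significance is assessed by randomization: fitness values are
permuted across maternal lines for the linear gradients, and first-order
residuals are permuted (keeping the fitted linear part) for the nonlinear
gradients. The canonical analysis is the symmetric eigendecomposition of
the doubled gamma matrix; mixed-sign eigenvalues indicate a saddle-shaped
surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAITS = ("maximum", "sensitivity", "reactivity")


def fitness_proxy(age_first_repro, clutch_size):
    """w = ln(clutch_size / age_first_repro); vectorized."""
    age = np.asarray(age_first_repro, dtype=float)
    clutch = np.asarray(clutch_size, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age at first reproduction must be > 0 days")
    if np.any(clutch < 1):
        raise ValueError("clutch size must be >= 1")
    w = np.log(clutch / age)
    return float(w) if w.ndim == 0 else w


def fitness_per_line(lifehistory: pd.DataFrame) -> pd.DataFrame:
    """Mean fitness proxy per maternal line (clone, mother).

    Traits exist per maternal line, so the line is the unit of the selection
    analysis; each replicate's proxy is averaged within its line.
    """
    lh = lifehistory.copy()
    lh["w"] = fitness_proxy(lh["age_first_repro"], lh["clutch_size"])
    return (lh.groupby(["clone", "pond", "mother"], sort=False, observed=True)["w"]
            .mean().reset_index())


def _second_order_design(Z: np.ndarray):
    """Columns: 1, z1..z3, z1^2..z3^2, z1z2, z1z3, z2z3."""
    n, t = Z.shape
    cols = [np.ones(n)]
    cols += [Z[:, k] for k in range(t)]
    cols += [Z[:, k] ** 2 for k in range(t)]
    pairs = [(a, b) for a in range(t) for b in range(a + 1, t)]
    cols += [Z[:, a] * Z[:, b] for a, b in pairs]
    return np.column_stack(cols), pairs


def _check_rank(X: np.ndarray, names):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify collinear columns by testing each against the rest
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            proj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            if np.allclose(others @ proj, X[:, j], atol=1e-8):
                bad.append(names[j])
        raise ValueError(f"rank-deficient regression design; collinear columns: {bad}")


def _gamma_from_coefs(coefs: np.ndarray, pairs, t=3):
    """Assemble gamma (doubled diagonal) from second-order coefficients
    ordered as [intercept, linear(t), quadratic(t), cross(pairs)]."""
    gamma = np.zeros((t, t))
    quad = coefs[1 + t: 1 + 2 * t]
    for k in range(t):
        gamma[k, k] = 2.0 * quad[k]
    cross = coefs[1 + 2 * t:]
    for (a, b), c in zip(pairs, cross):
        gamma[a, b] = gamma[b, a] = c
    return gamma


@dataclass
class SelectionSurface:
    """Estimated directional and quadratic selection on the three traits."""

    beta: np.ndarray                  # (3,)
    gamma: np.ndarray                 # (3, 3), diagonal doubled
    gamma_raw: np.ndarray             # (3, 3), diagonal as fitted
    p_beta: np.ndarray | None = None
    p_gamma: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    M: np.ndarray | None = None
    p_lambda: np.ndarray | None = None
    n: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def surface_shape(self) -> str:
        """'saddle' when the canonical curvatures have mixed signs."""
        if self.lambdas is None:
            raise ValueError("run canonical_analysis first")
        lam = self.lambdas[np.abs(self.lambdas) > 1e-12]
        if lam.size == 0:
            return "flat"
        if np.all(lam > 0):
            return "bowl"
        if np.all(lam < 0):
            return "dome"
        return "saddle"


def fit_selection_surface(traits_std: pd.DataFrame, w: np.ndarray,
                          trait_cols=TRAITS) -> SelectionSurface:
    """Estimate beta and gamma on standardized traits.

    Parameters
    ----------
    traits_std
        Standardized trait table (one row per maternal line).
    w
        Fitness proxy per row, aligned with ``traits_std``.
    """
    Z = traits_std.loc[:, list(trait_cols)].to_numpy(dtype=float)
    w = np.asarray(w, dtype=float)
    n, t = Z.shape
    if n < 10:
        raise ValueError("need >= 10 maternal lines for the quadratic fit")
    if w.shape != (n,):
        raise ValueError("w must align with the trait table rows")

    X1 = np.column_stack([np.ones(n), Z])
    _check_rank(X1, ["intercept", *trait_cols])
    beta = np.linalg.lstsq(X1, w, rcond=None)[0][1:]

    X2, pairs = _second_order_design(Z)
    names2 = (["intercept", *trait_cols]
              + [f"{c}^2" for c in trait_cols]
              + [f"{trait_cols[a]}:{trait_cols[b]}" for a, b in pairs])
    _check_rank(X2, names2)
    coefs2 = np.linalg.lstsq(X2, w, rcond=None)[0]
    gamma = _gamma_from_coefs(coefs2, pairs, t)
    gamma_raw = gamma.copy()
    np.fill_diagonal(gamma_raw, np.diag(gamma) / 2.0)
    return SelectionSurface(beta=beta, gamma=gamma, gamma_raw=gamma_raw, n=n)


def randomization_test(traits_std: pd.DataFrame, w: np.ndarray,
                       surface: SelectionSurface, B: int = 10_000,
                       seed: int | None = None,
                       trait_cols=TRAITS) -> SelectionSurface:
    """Permutation p-values for beta, gamma and the canonical curvatures.

    Linear gradients: w is reallocated at random across maternal lines and
    the first-order model refit B times. Nonlinear gradients: the
    first-order residuals are permuted and added back to the first-order
    fitted values before refitting the second-order model, honouring the
    dependence of the quadratic terms on the linear fit. Two-tailed
    p = (1 + #{|perm| >= |obs|}) / (B + 1); eigenvalue p-values compare
    rank-matched null eigenvalues under the same residual scheme.
    """
    if B < 99:
        raise ValueError("B must be >= 99 for a meaningful permutation test")
    rng = np.random.default_rng(seed)
    Z = traits_std.loc[:, list(trait_cols)].to_numpy(dtype=float)
    w = np.asarray(w, dtype=float)
    n, t = Z.shape

    X1 = np.column_stack([np.ones(n), Z])
    X2, pairs = _second_order_design(Z)
    pinv1 = np.linalg.pinv(X1)
    pinv2 = np.linalg.pinv(X2)

    coefs1 = pinv1 @ w
    fitted1 = X1 @ coefs1
    resid1 = w - fitted1

    # linear: full reallocation of w
    perm_idx = np.argsort(rng.random((B, n)), axis=1)
    W_perm = w[perm_idx]                       # (B, n)
    beta_perm = (pinv1 @ W_perm.T)[1:].T       # (B, t)

    # nonlinear: permute residuals around the linear fit
    R_perm = resid1[np.argsort(rng.random((B, n)), axis=1)]
    W_resid = fitted1 + R_perm
    coefs2_perm = (pinv2 @ W_resid.T).T        # (B, 10)

    obs_beta = np.abs(surface.beta)
    p_beta = (1 + (np.abs(beta_perm) >= obs_beta).sum(axis=0)) / (B + 1)

    gamma_perm = np.empty((B, t, t))
    for i in range(B):
        gamma_perm[i] = _gamma_from_coefs(coefs2_perm[i], pairs, t)
    p_gamma = (1 + (np.abs(gamma_perm) >= np.abs(surface.gamma)).sum(axis=0)) / (B + 1)

    lambdas, M = canonical_analysis(surface.gamma)
    lam_perm = np.sort(np.linalg.eigvalsh(gamma_perm), axis=1)[:, ::-1]
    p_lambda = (1 + (np.abs(lam_perm) >= np.abs(lambdas)).sum(axis=0)) / (B + 1)

    surface.p_beta = p_beta
    surface.p_gamma = p_gamma
    surface.lambdas = lambdas
    surface.M = M
    surface.p_lambda = p_lambda
    surface.meta.update({"B": B, "scheme": "w-permutation (linear), "
                         "residual permutation (nonlinear)"})
    return surface


def canonical_analysis(gamma: np.ndarray):
    """Canonical rotation of the quadratic selection surface.

    Returns the curvatures ``lambdas`` (eigenvalues of gamma, sorted
    descending) and the axis matrix ``M`` whose columns are unit
    eigenvectors, each signed so its largest-magnitude loading is positive.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.shape[0] != gamma.shape[1]:
        raise ValueError("gamma must be square")
    if not np.allclose(gamma, gamma.T, atol=1e-10):
        raise ValueError("gamma must be symmetric")
    lam, vecs = np.linalg.eigh(gamma)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    M = vecs[:, order]
    for k in range(M.shape[1]):
        j = np.argmax(np.abs(M[:, k]))
        if M[j, k] < 0:
            M[:, k] = -M[:, k]
    return lam, M


def analyze_pond(traits: pd.DataFrame, lifehistory: pd.DataFrame, pond: str,
                 B: int = 10_000, seed: int | None = None) -> SelectionSurface:
    """Full selection analysis for one pond: standardize its trait table,
    attach per-line fitness, fit the surface and run the randomization test."""
    from .gmatrix import standardize_traits

    sub = traits[traits["pond"] == pond]
    if sub.empty:
        raise ValueError(f"no trait rows for pond {pond!r}")
    sub_std, record = standardize_traits(sub)
    wtab = fitness_per_line(lifehistory[lifehistory["pond"] == pond])
    merged = sub_std.merge(wtab, on=["clone", "pond", "mother"], how="inner")
    if len(merged) < len(sub_std):
        raise ValueError("life-history rows missing for some maternal lines")
    surface = fit_selection_surface(merged, merged["w"].to_numpy())
    surface = randomization_test(merged, merged["w"].to_numpy(), surface,
                                 B=B, seed=seed)
    surface.meta["pond"] = pond
    surface.meta["standardization"] = record
    return surface
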