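"""Three-parameter logistic reaction norms.

Each maternal line's induction levels along the predator-cue gradient are
summarized by a sigmoid

    y(x) = A / (1 + exp((m - x) / s))

whose parameters are the three traits analysed downstream: the asymptote
``A`` (*maximum*, induction units 0-100), the inflection ``m``
(*sensitivity*, cue dose in ul/ml at which induction reaches A/2) and the
scale ``s`` (*reactivity*, ul/ml; a small scale means a steep, threshold-like
response).

Fitting is bounded nonlinear least squares with a deterministic multi-start
over inflection and scale candidates; ties are broken by residual sum of
squares, then by the smaller scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

#: Multi-start candidates for the scale parameter (ul/ml).
SCALE_STARTS = (0.02, 0.1, 0.5)

#: Bounds: asymptote may slightly overshoot the 0-100 score range.
A_BOUNDS = (0.0, 120.0)
S_BOUNDS = (1e-4, 2.0)


def three_param_logistic(x, maximum, sensitivity, reactivity):
    """Evaluate the sigmoid A / (1 + exp((m - x)/s))."""
    x = np.asarray(x, dtype=float)
    z = (sensitivity - x) / reactivity
    # clip avoids overflow in exp for extreme starts; saturates the sigmoid
    return maximum / (1.0 + np.exp(np.clip(z, -500.0, 500.0)))


@dataclass
class ReactionNormParams:
    """Fitted traits and diagnostics for one maternal line."""

    maximum: float
    sensitivity: float
    reactivity: float
    rss: float
    converged: bool
    identifiable: bool = True
    n_obs: int = 0

    def predict(self, x):
        return three_param_logistic(x, self.maximum, self.sensitivity, self.reactivity)


def _constant_fit_ss(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2))


def fit_three_param_logistic(doses, inductions) -> ReactionNormParams:
    """Fit the three-parameter logistic to one maternal line's data.

    Parameters
    ----------
    doses
        Cue concentrations (ul/ml), >= 4 distinct values.
    inductions
        Induction levels in [0, 100], one per dose entry (>= 7 observations).

    Returns
    -------
    ReactionNormParams
        Best multi-start solution; ``identifiable`` is False (and the
        parameters are NaN) when the response carries no information, i.e.
        all induction values are identical.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(inductions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and inductions must be 1-D arrays of equal length")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct doses to identify three parameters")
    if x.size < 7:
        raise ValueError("need >= 7 observations")

    if np.ptp(y) == 0.0:
        return ReactionNormParams(np.nan, np.nan, np.nan, 0.0, False,
                                  identifiable=False, n_obs=x.size)

    m_hi = 2.0 * float(x.max())
    lower = np.array([A_BOUNDS[0], 0.0, S_BOUNDS[0]])
    upper = np.array([A_BOUNDS[1], m_hi, S_BOUNDS[1]])

    def resid(theta):
        return three_param_logistic(x, *theta) - y

    a0 = float(np.clip(y.max(), 1.0, A_BOUNDS[1]))
    best = None
    for m0 in np.unique(x):
        for s0 in SCALE_STARTS:
            theta0 = np.clip([a0, m0, s0], lower + 1e-12, upper - 1e-12)
            try:
                sol = least_squares(resid, theta0, bounds=(lower, upper),
                                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:  # pragma: no cover - defensive
                continue
            if not sol.success:
                continue
            rss = float(np.sum(sol.fun ** 2))
            cand = (rss, float(sol.x[2]), sol.x)
            if best is None or cand[:2] < best[:2]:
                best = cand

    const_ss = _constant_fit_ss(y)
    if best is None or best[0] > const_ss + 1e-8 * max(const_ss, 1.0):
        # no start converged to something at least as good as a flat line
        return ReactionNormParams(np.nan, np.nan, np.nan,
                                  best[0] if best else np.nan, False,
                                  identifiable=True, n_obs=x.size)
    rss, _, theta = best
    return ReactionNormParams(float(theta[0]), float(theta[1]), float(theta[2]),
                              rss, True, identifiable=True, n_obs=x.size)


def build_trait_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Fit one reaction norm per maternal line of a scored induction table.

    Parameters
    ----------
    scored
        Per-individual table with columns ``clone, pond, mother,
        concentration, induction``.

    Returns
    -------
    pandas.DataFrame
        One row per (clone, mother) with the three traits and diagnostics;
        lines whose fit is non-identifiable or fails to converge are excluded
        and logged.
    """
    required = {"clone", "pond", "mother", "concentration", "induction"}
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored table missing columns: {sorted(missing)}")

    rows = []
    for (clone, pond, mother), grp in scored.groupby(
            ["clone", "pond", "mother"], sort=False, observed=True):
        if grp["concentration"].nunique() < 4:
            log.warning("maternal line (%s, %s): only %d distinct doses, skipped",
                        clone, mother, grp["concentration"].nunique())
            continue
        fit = fit_three_param_logistic(grp["concentration"].to_numpy(),
                                       grp["induction"].to_numpy())
        if not fit.converged:
            reason = "non-identifiable (flat response)" if not fit.identifiable \
                else "optimizer failed from all starts"
            log.warning("maternal line (%s, %s): %s, excluded", clone, mother, reason)
            continue
        rows.append({
            "clone": clone, "pond": pond, "mother": mother,
            "maximum": fit.maximum, "sensitivity": fit.sensitivity,
            "reactivity": fit.reactivity, "rss": fit.rss,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows, columns=["clone", "pond", "mother", "maximum",
                                       "sensitivity", "reactivity", "rss",
                                       "converged"])
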