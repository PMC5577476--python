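"""Neckteeth induction scoring.

Raw morphological observations record, per individual and juvenile instar,
the pedestal class (absent / small / large) and the number of spikes.
These are converted to a points score (pedestal points plus 10 per spike),
reduced to the maximum over instars for each individual, and normalized to
a 0-100 induction level against the maximum score in the dataset (or a
fixed reference maximum for cross-dataset comparability).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Points assigned to each pedestal class.
PEDESTAL_POINTS = {"absent": 0, "small": 30, "large": 50}

#: Points per spike.
SPIKE_POINTS = 10

#: Reference maximum raw score (a large pedestal with eight spikes), usable
#: as a fixed normalization constant instead of the observed dataset maximum.
REFERENCE_MAX_SCORE = 130


def score_observation(pedestal: str, spikes: int) -> int:
    """Raw induction points for one instar observation.

    Parameters
    ----------
    pedestal
        Pedestal class, one of ``"absent"``, ``"small"``, ``"large"``.
    spikes
        Non-negative spike count.

    Returns
    -------
    int
        ``pedestal points + 10 * spikes``.
    """
    try:
        base = PEDESTAL_POINTS[pedestal]
    except KeyError:
        raise ValueError(
            f"unknown pedestal class {pedestal!r}; "
            f"expected one of {sorted(PEDESTAL_POINTS)}"
        ) from None
    spikes = int(spikes)
    if spikes < 0:
        raise ValueError(f"spike count must be >= 0, got {spikes}")
    return base + SPIKE_POINTS * spikes


def max_across_instars(raw_scores) -> float:
    """Maximal raw score over an individual's instar observations.

    Induction is analysed as the strongest expression shown in any juvenile
    instar, regardless of which instar it occurred in.
    """
    scores = np.asarray(list(raw_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no instar observations supplied")
    return float(scores.max())


def normalize_scores(raw, normalization_max: float):
    """Normalize raw scores to 0-100 induction levels.

    Parameters
    ----------
    raw
        Scalar or array of raw scores.
    normalization_max
        Positive maximum raw score defining induction level 100.
    """
    if normalization_max <= 0:
        raise ValueError("normalization_max must be > 0")
    arr = np.asarray(raw, dtype=float)
    if np.any(arr > normalization_max):
        bad = float(arr.max())
        raise ValueError(
            f"raw score {bad} exceeds normalization maximum {normalization_max}; "
            "scoring inconsistency"
        )
    if np.any(arr < 0):
        raise ValueError("raw scores must be >= 0")
    out = 100.0 * arr / normalization_max
    return float(out) if np.isscalar(raw) else out


def score_table(induction: pd.DataFrame, fixed_max: float | None = None) -> pd.DataFrame:
    """Score a per-instar induction table into per-individual induction levels.

    Parameters
    ----------
    induction
        Long table with columns ``clone, pond, mother, individual, instar,
        concentration, pedestal, spikes`` (one row per individual x instar).
    fixed_max
        If given, normalize against this raw score instead of the observed
        dataset maximum (e.g. ``REFERENCE_MAX_SCORE`` = 130).

    Returns
    -------
    pandas.DataFrame
        One row per individual with ``raw_score`` (max over instars) and
        ``induction`` in [0, 100].
    """
    required = {"clone", "pond", "mother", "individual", "instar",
                "concentration", "pedestal", "spikes"}
    missing = required - set(induction.columns)
    if missing:
        raise ValueError(f"induction table missing columns: {sorted(missing)}")
    if induction.empty:
        raise ValueError("empty induction table")

    df = induction.copy()
    df["instar_score"] = [
        score_observation(p, s) for p, s in zip(df["pedestal"], df["spikes"])
    ]
    keys = ["clone", "pond", "mother", "individual", "concentration"]
    scored = (
        df.groupby(keys, sort=False, observed=True)["instar_score"]
        .max()
        .rename("raw_score")
        .reset_index()
    )
    norm_max = float(fixed_max) if fixed_max is not None else float(scored["raw_score"].max())
    if norm_max <= 0:
        # dataset entirely uninduced: define induction as 0 everywhere
        scored["induction"] = 0.0
    else:
        scored["induction"] = normalize_scores(scored["raw_score"].to_numpy(), norm_max)
    scored.attrs["normalization_max"] = norm_max
    return scored
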