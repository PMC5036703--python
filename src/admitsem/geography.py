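"""Practice-to-area aggregation of latent scores via a population crosswalk.

Neighbourhood (e.g. LSOA) scores are population-weighted averages of the
scores of the practices serving each area.  Aggregation is linear, so it
can be applied to posterior draws (propagating uncertainty into an area
SD) or to posterior means; the two agree on the mean exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CrosswalkMatrix

__all__ = ["aggregate_to_areas"]


def aggregate_to_areas(
    scores: np.ndarray,
    crosswalk: CrosswalkMatrix,
    practice_id: list[str] | None = None,
) -> pd.DataFrame:
    """Weighted-average practice scores into area scores.

    Parameters
    ----------
    scores : array, shape (I,) or (n_draws, I)
        Per-practice scores, or posterior draws of them.
    crosswalk : CrosswalkMatrix
        Row-stochastic area-by-practice weights.  Rows that originally
        summed to less than 1 were renormalized on construction; the raw
        sum is reported as ``covered_fraction``.
    practice_id : list of str, optional
        Practice labels for the columns of ``scores``; when given, they are
        aligned to the crosswalk's practice order, and a crosswalk practice
        absent from the scores is an error naming it.

    Returns
    -------
    DataFrame with one row per area: ``score_mean``, ``score_sd`` (NaN when
    a single score vector is supplied), ``covered_fraction``.
    """
    scores = np.asarray(scores, dtype=float)
    single = scores.ndim == 1
    if single:
        scores = scores[None, :]
    if scores.ndim != 2:
        raise ValueError("scores must be 1-D (per practice) or 2-D (draws x practice)")
    if practice_id is not None:
        index = {p: i for i, p in enumerate(practice_id)}
        missing = [p for p in crosswalk.practice_id if p not in index]
        if missing:
            raise ValueError(f"crosswalk practices absent from scores: {missing}")
        scores = scores[:, [index[p] for p in crosswalk.practice_id]]
    if scores.shape[1] != len(crosswalk.practice_id):
        raise ValueError(
            f"score vector length {scores.shape[1]} does not match crosswalk "
            f"practice count {len(crosswalk.practice_id)}"
        )
    area = scores @ crosswalk.weights.T  # (n_draws, L)
    return pd.DataFrame(
        {
            "area_id": crosswalk.area_id,
            "score_mean": area.mean(axis=0),
            "score_sd": np.full(crosswalk.L, np.nan) if single else area.std(axis=0, ddof=1),
            "covered_fraction": crosswalk.covered_fraction,
        }
    ).set_index("area_id")
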