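"""Kim-Park scoring and selection of metagene-specific features.

Each feature (row of W) is scored by how concentrated its contribution is on
a single metagene: with ``p_iq = W_iq / sum_q W_iq``,

    score_i = 1 + (1 / log2 r) * sum_q p_iq * log2 p_iq

so a row loading a single metagene scores 1 and a uniform row scores 0.
Features are selected when (a) their score strictly exceeds the threshold
``s = mu + 3 sigma``, where ``mu`` and ``sigma`` are the median and the
*unscaled* median absolute deviation of the scores, and (b) their maximal
contribution in W strictly exceeds the median of all entries of W.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special

from .model_core import ConfigurationError


@dataclass
class FeatureSelection:
    """Scores, threshold and the selected feature indices (0-based)."""

    scores: np.ndarray
    threshold_s: float
    mu: float
    sigma: float
    selected: np.ndarray
    n_selected: int
    feature_ids: Optional[list[str]] = None


def feature_scores(W) -> np.ndarray:
    """Metagene-specificity score per row of W, in [0, 1].

    Rows are normalized to sum to one before the entropy computation, so
    scores are invariant to positive rescaling of any row.  All-zero rows
    contribute to no metagene and score 0 by convention.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ConfigurationError("feature scoring requires a matrix with rank >= 2")
    r = W.shape[1]
    rows = W.sum(axis=1)
    scores = np.zeros(W.shape[0])
    ok = rows > 0
    P = W[ok] / rows[ok, None]
    ent = special.xlogy(P, P).sum(axis=1) / np.log(2.0)  # sum p log2 p (<= 0)
    scores[ok] = 1.0 + ent / np.log2(r)
    return np.clip(scores, 0.0, 1.0)


def select_features(W, feature_ids: Optional[Sequence[str]] = None) -> FeatureSelection:
    """Kim-Park two-condition feature selection.

    The threshold is ``s = median(scores) + 3 * MAD(scores)`` with the raw
    (unscaled) median absolute deviation -- no 1.4826 consistency factor.
    Both selection conditions are strict inequalities.
    """
    W = np.asarray(W, dtype=float)
    scores = feature_scores(W)
    mu = float(np.median(scores))
    sigma = float(np.median(np.abs(scores - mu)))
    s = mu + 3.0 * sigma
    global_median = float(np.median(W))
    cond_score = scores > s
    cond_contrib = W.max(axis=1) > global_median
    selected = np.flatnonzero(cond_score & cond_contrib)
    return FeatureSelection(
        scores=scores,
        threshold_s=s,
        mu=mu,
        sigma=sigma,
        selected=selected,
        n_selected=int(selected.size),
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )
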