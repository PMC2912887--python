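"""Factorization-rank survey and the published selection heuristics.

The rank ``r`` (number of metagenes) is the one free structural parameter of
NMF.  The survey fits the data at each candidate rank with repeated runs and
records cluster stability (cophenetic correlation of the consensus matrix)
and reconstruction quality (best-fit RSS / explained variance).  Three
selection rules are implemented:

* Brunet: smallest rank at which the cophenetic coefficient starts
  decreasing;
* RSS inflection (Hutchins): rank at the inflection point of the RSS curve;
* Frigyesi: largest rank for which the marginal RSS decrease still exceeds
  the decrease observed on randomized (within-column permuted) data.

A residual-weighted consensus matrix (runs weighted by inverse RSS) supports
the Frigyesi-style stability assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ConfigurationError,
    DomainError,
    FitResult,
    TargetMatrix,
    as_target,
    logger,
)
from .algorithms import StoppingRule, multifit, stationarity
from .metrics import connectivity, cophenetic_coefficient, evar, rss
from .model_core import predict_clusters


@dataclass
class RankSurvey:
    """Per-rank quality measures for observed (and optionally randomized) data."""

    ranks: list[int]
    nrun: int
    method: str
    cophenetic: list[float]
    rss_best: list[float]
    evar_best: list[float]
    consensus: list[np.ndarray]
    randomized: Optional["RankSurvey"] = None
    weighted_cophenetic: Optional[list[float]] = None

    def as_frame(self) -> pd.DataFrame:
        """Per-rank table (one row per surveyed rank)."""
        df = pd.DataFrame(
            {
                "rank": self.ranks,
                "cophenetic": self.cophenetic,
                "rss_best": self.rss_best,
                "evar_best": self.evar_best,
            }
        )
        if self.weighted_cophenetic is not None:
            df["weighted_cophenetic"] = self.weighted_cophenetic
        if self.randomized is not None:
            df["rss_best_random"] = self.randomized.rss_best
            df["cophenetic_random"] = self.randomized.cophenetic
        return df


def _safe_cophenetic(consensus: np.ndarray) -> float:
    try:
        return cophenetic_coefficient(consensus)
    except DomainError as exc:
        warnings.warn(f"cophenetic coefficient not available: {exc}", stacklevel=3)
        return float("nan")


def survey(
    X,
    ranks: Sequence[int],
    method: str = "brunet",
    nrun: int = 30,
    master_seed: Optional[int] = None,
    stop: Optional[StoppingRule] = None,
    seed: str = "random",
    weighted: bool = False,
    randomized: bool = False,
    n_jobs: int = 1,
    **options,
) -> RankSurvey:
    """Fit ``X`` at each candidate rank and record quality measures.

    30-50 runs per rank give a robust estimate; the default stopping rule for
    survey fits is objective stationarity, which behaves uniformly on both
    structured and randomized data.  Deterministic given ``master_seed``.
    With ``randomized=True`` the same survey is repeated on a within-column
    permutation of ``X`` and attached as ``.randomized``.
    """
    Xt = as_target(X)
    ranks = [int(r) for r in ranks]
    if any(r < 2 for r in ranks):
        raise ConfigurationError("surveyed ranks must be >= 2")
    if sorted(ranks) != ranks or len(set(ranks)) != len(ranks):
        raise ConfigurationError("ranks must be strictly increasing")
    if stop is None:
        stop = stationarity()
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(ranks) + 1)
    rank_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children[:-1]]
    aux_seed = int(children[-1].generate_state(1)[0] % 2**31)

    coph, rss_best, evar_best, consensus, wcoph = [], [], [], [], []
    for r, rseed in zip(ranks, rank_seeds):
        mf = multifit(
            Xt, r, method=method, nrun=nrun, master_seed=rseed, seed=seed,
            stop=stop, n_jobs=n_jobs, **options,
        )
        coph.append(_safe_cophenetic(mf.consensus))
        rss_best.append(rss(Xt, mf.best.model))
        evar_best.append(evar(Xt, mf.best.model))
        consensus.append(mf.consensus)
        if weighted:
            wc = weighted_consensus(mf.fits, Xt)
            wcoph.append(_safe_cophenetic(wc))
        logger.info(
            "rank %d: cophenetic=%.4f rss_best=%.4g", r, coph[-1], rss_best[-1]
        )
    result = RankSurvey(
        ranks=ranks,
        nrun=nrun,
        method=method,
        cophenetic=coph,
        rss_best=rss_best,
        evar_best=evar_best,
        consensus=consensus,
        weighted_cophenetic=wcoph if weighted else None,
    )
    if randomized:
        Xp = randomize_columns(Xt, rng_seed=aux_seed)
        result.randomized = survey(
            Xp, ranks, method=method, nrun=nrun, master_seed=aux_seed,
            stop=stop, seed=seed, weighted=weighted, randomized=False,
            n_jobs=n_jobs, **options,
        )
    return result


def randomize_columns(X, rng_seed: Optional[int] = None) -> TargetMatrix:
    """Permute entries independently within each column of X.

    Destroys the across-feature covariation that NMF exploits while
    preserving every column's marginal distribution (column sums exactly).
    """
    Xt = as_target(X)
    rng = np.random.default_rng(rng_seed)
    values = Xt.values.copy()
    for j in range(values.shape[1]):
        values[:, j] = values[rng.permutation(values.shape[0]), j]
    return TargetMatrix(values, Xt.feature_ids, Xt.sample_ids, Xt.class_labels)


def randomized_survey(
    X,
    ranks: Sequence[int],
    method: str = "brunet",
    nrun: int = 30,
    master_seed: Optional[int] = None,
    **options,
) -> RankSurvey:
    """Survey of a within-column permutation of X (the overfitting baseline)."""
    Xp = randomize_columns(X, rng_seed=master_seed)
    return survey(Xp, ranks, method=method, nrun=nrun, master_seed=master_seed, **options)


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------


def select_rank_brunet(surv: RankSurvey) -> int:
    """Smallest rank at which the cophenetic coefficient starts decreasing.

    Returns the smallest surveyed ``r`` with ``cophenetic(r+1) < cophenetic(r)``
    between consecutive surveyed ranks; if the coefficient never decreases,
    the largest surveyed rank is returned with a warning.
    """
    if len(surv.ranks) < 2:
        raise ConfigurationError("need at least two surveyed ranks")
    c = surv.cophenetic
    for i in range(len(c) - 1):
        if c[i + 1] < c[i]:
            return surv.ranks[i]
    warnings.warn(
        "cophenetic coefficient never decreases over the surveyed ranks; "
        "returning the largest surveyed rank",
        stacklevel=2,
    )
    return surv.ranks[-1]


def select_rank_rss_inflection(surv: RankSurvey) -> int:
    """Rank at the inflection point of the best-fit RSS curve.

    The discrete curvature (second difference) of RSS over the surveyed grid
    is maximized; a flat/linear decline has no distinct inflection, in which
    case the smallest interior rank is returned with a warning.
    """
    if len(surv.ranks) < 3:
        raise ConfigurationError("need at least three surveyed ranks")
    r = np.asarray(surv.rss_best, dtype=float)
    d2 = r[:-2] - 2.0 * r[1:-1] + r[2:]  # curvature at interior ranks
    scale = max(abs(r[0] - r[-1]), 1.0)
    if d2.max() - d2.min() <= 1e-9 * scale:
        warnings.warn(
            "RSS declines without a distinct inflection point; returning the "
            "smallest interior rank",
            stacklevel=2,
        )
        return surv.ranks[1]
    return surv.ranks[1 + int(np.argmax(d2))]


def select_rank_frigyesi(surv: RankSurvey) -> int:
    """Largest rank whose marginal RSS decrease beats the randomized baseline.

    With ``dRSS(r_i) = RSS(r_{i-1}) - RSS(r_i)`` on the common grid, returns
    the largest surveyed rank ``r_i`` such that the observed decrease exceeds
    the randomized-data decrease at every rank up to ``r_i``.  If even the
    first decrease does not, the smallest surveyed rank is returned with a
    warning.
    """
    if surv.randomized is None:
        raise ConfigurationError("survey lacks randomized results; rerun with randomized=True")
    if surv.randomized.ranks != surv.ranks:
        raise ConfigurationError("observed and randomized surveys use different rank grids")
    obs = np.asarray(surv.rss_best, dtype=float)
    rnd = np.asarray(surv.randomized.rss_best, dtype=float)
    d_obs = obs[:-1] - obs[1:]
    d_rnd = rnd[:-1] - rnd[1:]
    best = None
    for i in range(len(d_obs)):
        if d_obs[i] > d_rnd[i]:
            best = surv.ranks[i + 1]
        else:
            break
    if best is None:
        warnings.warn(
            "observed marginal RSS decrease never exceeds the randomized baseline; "
            "returning the smallest surveyed rank",
            stacklevel=2,
        )
        return surv.ranks[0]
    return best


def weighted_consensus(fits: Sequence[FitResult], X) -> np.ndarray:
    """Consensus matrix with runs weighted by their relative residual error.

    Weight of run k is ``(1/RSS_k) / sum_j (1/RSS_j)``: better-fitting runs
    count more.  Any exact fit (RSS = 0) takes all the weight (shared equally
    among exact fits), the limit of the inverse-RSS weighting.
    """
    if not fits:
        raise ConfigurationError("need at least one fit")
    Xt = as_target(X)
    residuals = np.array([rss(Xt, f.model) for f in fits])
    conns = [connectivity(predict_clusters(f.model, axis="samples")) for f in fits]
    if np.any(residuals == 0.0):
        w = (residuals == 0.0).astype(float)
    else:
        w = 1.0 / residuals
    w = w / w.sum()
    return np.tensordot(w, np.array(conns), axes=1)
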