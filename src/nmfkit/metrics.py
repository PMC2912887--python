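"""Quality measures for NMF fits and the consensus-clustering machinery.

Reconstruction: residual sum of squares (RSS) and explained variance
``evar = 1 - RSS / sum(X^2)``.  Factor structure: Hoyer's sparseness.
External clustering quality against known sample classes: purity and
entropy.  Cluster stability across stochastic runs: connectivity matrices,
their average (the consensus matrix) and the cophenetic correlation
coefficient of the consensus.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from .model_core import (
    DimensionError,
    DomainError,
    MultiFitResult,
    NMFModel,
    TargetMatrix,
    as_target,
    estimate,
    predict_clusters,
)


# ---------------------------------------------------------------------------
# Reconstruction quality
# ---------------------------------------------------------------------------


def rss(X, model: NMFModel) -> float:
    """Residual sum of squares between X and the model estimate.

    Unhalved: ``rss == 2 * objective(..., metric='euclidean')``.
    """
    Xv = as_target(X).values
    est = estimate(model)
    if est.shape != Xv.shape:
        raise DimensionError(
            f"estimate shape {est.shape} does not match data shape {Xv.shape}"
        )
    return float(np.sum((Xv - est) ** 2))


def evar(X, model: NMFModel) -> float:
    """Explained variance ``1 - RSS / sum(X_ij^2)``."""
    Xv = as_target(X).values
    total = float(np.sum(Xv**2))
    if total == 0.0:
        raise DomainError("explained variance is undefined for an all-zero target")
    return 1.0 - rss(X, model) / total


# ---------------------------------------------------------------------------
# Sparseness (Hoyer)
# ---------------------------------------------------------------------------


def sparseness(x) -> float:
    """Hoyer's sparseness of a vector, in [0, 1].

    ``(sqrt(n) - |x|_1 / |x|_2) / (sqrt(n) - 1)``: 0 for a constant vector,
    1 for a vector with a single nonzero entry.
    """
    v = np.asarray(x, dtype=float).ravel()
    n = v.size
    if n < 2:
        raise DomainError("sparseness is undefined for vectors of length < 2")
    l2 = np.linalg.norm(v)
    if l2 == 0.0:
        raise DomainError("sparseness is undefined for the zero vector")
    l1 = np.abs(v).sum()
    sq = np.sqrt(n)
    return float((sq - l1 / l2) / (sq - 1.0))


def model_sparseness(model: NMFModel) -> tuple[float, float]:
    """Mean Hoyer sparseness over columns of W and over rows of H."""
    sw = float(np.mean([sparseness(model.W[:, j]) for j in range(model.rank)]))
    sh = float(np.mean([sparseness(model.H[i, :]) for i in range(model.rank)]))
    return sw, sh


# ---------------------------------------------------------------------------
# External clustering quality
# ---------------------------------------------------------------------------


def _contingency(clusters, labels) -> np.ndarray:
    cl = np.asarray(clusters)
    lb = np.asarray(labels)
    if cl.shape[0] != lb.shape[0]:
        raise DimensionError(
            f"clusters ({cl.shape[0]}) and labels ({lb.shape[0]}) differ in length"
        )
    _, ci = np.unique(cl, return_inverse=True)
    _, li = np.unique(lb, return_inverse=True)
    table = np.zeros((ci.max() + 1, li.max() + 1), dtype=int)
    np.add.at(table, (ci, li), 1)
    return table


def purity(clusters, labels) -> float:
    """Fraction of samples belonging to the majority class of their cluster."""
    table = _contingency(clusters, labels)
    p = table.sum()
    if p == 0:
        raise DimensionError("empty assignment")
    return float(table.max(axis=1).sum() / p)


def entropy(clusters, labels) -> float:
    """Normalized class entropy within clusters; 0 = perfect, 1 = maximal mixing."""
    table = _contingency(clusters, labels)
    p = table.sum()
    q = table.shape[1]
    if q < 2:
        raise DomainError("entropy is undefined with a single class")
    total = 0.0
    for k in range(table.shape[0]):
        nk = table[k].sum()
        if nk == 0:
            continue
        nz = table[k][table[k] > 0].astype(float)
        total += float(np.sum(nz * np.log2(nz / nk)))
    return float(-total / (p * np.log2(q)) + 0.0)  # +0.0 normalizes -0.0


# ---------------------------------------------------------------------------
# Connectivity / consensus / cophenetic coefficient
# ---------------------------------------------------------------------------


def connectivity(clusters) -> np.ndarray:
    """Binary co-clustering matrix: entry (i, j) = 1 iff i and j share a cluster."""
    cl = np.asarray(clusters).ravel()
    return (cl[:, None] == cl[None, :]).astype(float)


def consensus_matrix(models: Sequence[NMFModel]) -> np.ndarray:
    """Average connectivity matrix over a set of fitted models."""
    mats = [connectivity(predict_clusters(m, axis="samples")) for m in models]
    return np.mean(mats, axis=0)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation coefficient of a consensus matrix.

    Treats ``1 - consensus`` as sample distances, clusters them with average
    linkage and returns the Pearson correlation between the original and the
    cophenetic distances.  Values near 1 indicate stable clusters; a perfect
    0/1 block consensus gives exactly 1.

    Raises
    ------
    DomainError
        When all off-diagonal entries are equal (correlation undefined).
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DimensionError("consensus must be a square matrix")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(D, checks=False)
    if d.size < 2 or np.allclose(d, d[0]):
        raise DomainError(
            "cophenetic coefficient not available: all off-diagonal consensus "
            "entries are equal"
        )
    Z = average(d)
    _, coph_d = cophenet(Z, d)
    return float(np.corrcoef(d, coph_d)[0, 1])


# ---------------------------------------------------------------------------
# Quality report (one row per compared method)
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "method",
    "seed",
    "metric",
    "rank",
    "evar",
    "sparseness_W",
    "sparseness_H",
    "purity",
    "entropy",
    "niter",
    "cpu_time_s",
]


@dataclass
class QualityReport:
    """One comparison-table row: method provenance plus quality measures.

    ``cpu_time_s`` is measured process time; it is reported for information
    only (hardware dependent).
    """

    method: str
    seed: str
    metric: str
    rank: int
    evar: float
    sparseness_W: float
    sparseness_H: float
    purity: Optional[float]
    entropy: Optional[float]
    niter: int
    cpu_time_s: float

    def to_dict(self) -> dict:
        return asdict(self)


def quality_report(X, fit_result, cpu_time_s: float = float("nan")) -> QualityReport:
    """Build a :class:`QualityReport` for one fit on ``X``.

    Purity and entropy are filled only when ``X`` carries class labels.
    """
    Xt = as_target(X)
    model = fit_result.model
    sw, sh = model_sparseness(model)
    pur = ent = None
    if Xt.class_labels is not None:
        cl = predict_clusters(model, axis="samples")
        pur = purity(cl, Xt.class_labels)
        if len(set(Xt.class_labels)) >= 2:
            ent = entropy(cl, Xt.class_labels)
    return QualityReport(
        method=fit_result.algorithm,
        seed=fit_result.seed_method,
        metric=fit_result.metric,
        rank=model.rank,
        evar=evar(Xt, model),
        sparseness_W=sw,
        sparseness_H=sh,
        purity=pur,
        entropy=ent,
        niter=fit_result.n_iterations,
        cpu_time_s=cpu_time_s,
    )


def reports_table(reports: Sequence[QualityReport]) -> pd.DataFrame:
    """Assemble reports into the standard comparison table.

    Purity/entropy columns are dropped when no report provides them
    (no class labels given).
    """
    df = pd.DataFrame([r.to_dict() for r in reports], columns=REPORT_COLUMNS)
    for col in ("purity", "entropy"):
        if df[col].isna().all():
            df = df.drop(columns=[col])
    return df
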