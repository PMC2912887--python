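"""Core data structures for nonnegative matrix factorization (NMF).

NMF approximates a nonnegative feature-by-sample matrix ``X`` (n x p) by the
product ``W @ H`` of two lower-rank nonnegative matrices: ``W`` (n x r) holds
the basis components -- *metagenes* in the expression-array setting -- and
``H`` (r x p) the mixture coefficients, i.e. the metagene expression profile
of each sample.  Two model variants extend the plain product:

* non-smooth NMF interposes a smoothing matrix
  ``S = (1 - theta) * I + (theta / r) * J`` (``J`` all ones) so that the
  estimate is ``W @ S @ H``; larger ``theta`` forces sparser factors;
* offset NMF adds a feature-wise constant vector, ``W @ H + b 1^T``, which
  absorbs expression levels common to every sample.

The quality of an approximation is measured either by the (halved) squared
Frobenius norm or by the generalized Kullback-Leibler divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import special

logger = logging.getLogger("nmfkit")

#: Epsilon added to denominators and logarithm arguments throughout the
#: package; keeps multiplicative updates well defined at exact zeros.
EPS: float = 2.0**-52


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class NMFError(Exception):
    """Base class for all package errors."""


class DimensionError(NMFError, ValueError):
    """Incompatible matrix shapes."""


class DomainError(NMFError, ValueError):
    """Values outside the nonnegative/finite domain."""


class ConfigurationError(NMFError, ValueError):
    """Invalid combination of options or parameters."""


class NumericalError(NMFError, ArithmeticError):
    """Non-finite objective or failed numerical subproblem."""


class DataError(NMFError, ValueError):
    """Malformed input data or file."""


# ---------------------------------------------------------------------------
# Target matrix
# ---------------------------------------------------------------------------


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise DimensionError(f"{name} must be 2-dimensional, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise DomainError(f"{name} has a non-finite entry at row {i + 1}, column {j + 1}")
    return arr


def _check_nonnegative(arr: np.ndarray, name: str) -> None:
    if arr.size and arr.min() < 0:
        i, j = np.argwhere(arr < 0)[0]
        raise DomainError(
            f"{name} has a negative entry ({arr[i, j]!r}) at row {i + 1}, column {j + 1}"
        )


@dataclass
class TargetMatrix:
    """A nonnegative feature x sample data matrix with identifiers.

    Parameters
    ----------
    values
        n x p array of nonnegative, finite reals (expression units, arbitrary).
    feature_ids, sample_ids
        Unique identifiers for the n rows and p columns.  Generated as
        ``f1..fn`` / ``s1..sp`` when omitted.
    class_labels
        Optional known class per sample (one label per column), used by the
        external clustering-quality measures (purity, entropy).
    """

    values: np.ndarray
    feature_ids: Optional[Sequence[str]] = None
    sample_ids: Optional[Sequence[str]] = None
    class_labels: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "target matrix")
        _check_nonnegative(self.values, "target matrix")
        n, p = self.values.shape
        if self.feature_ids is None:
            self.feature_ids = [f"f{i + 1}" for i in range(n)]
        else:
            self.feature_ids = [str(x) for x in self.feature_ids]
        if self.sample_ids is None:
            self.sample_ids = [f"s{j + 1}" for j in range(p)]
        else:
            self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.feature_ids) != n:
            raise DimensionError(
                f"expected {n} feature ids, got {len(self.feature_ids)}"
            )
        if len(self.sample_ids) != p:
            raise DimensionError(f"expected {p} sample ids, got {len(self.sample_ids)}")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise DataError(f"{name} ids are not unique")
        if self.class_labels is not None:
            self.class_labels = list(self.class_labels)
            if len(self.class_labels) != p:
                raise DimensionError(
                    f"expected {p} class labels, got {len(self.class_labels)}"
                )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def as_target(X) -> TargetMatrix:
    """Coerce an array-like or :class:`TargetMatrix` to a :class:`TargetMatrix`."""
    if isinstance(X, TargetMatrix):
        return X
    return TargetMatrix(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# NMF model
# ---------------------------------------------------------------------------


def smoothing_matrix(rank: int, theta: float) -> np.ndarray:
    """Non-smooth NMF smoothing matrix ``S = (1-theta) I + (theta/r) J``."""
    if not 0.0 <= theta <= 1.0:
        raise ConfigurationError(f"theta must lie in [0, 1], got {theta}")
    return (1.0 - theta) * np.eye(rank) + (theta / rank) * np.ones((rank, rank))


@dataclass
class NMFModel:
    """A fitted (or candidate) factorization ``X ~ W @ H``.

    ``theta`` marks a non-smooth model (estimate ``W @ S(theta) @ H``);
    ``offset`` marks an offset model (estimate ``W @ H + offset 1^T``).
    The two variants are mutually exclusive in this package.
    """

    W: np.ndarray
    H: np.ndarray
    offset: Optional[np.ndarray] = None
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        self.W = _as_float_array(self.W, "W")
        self.H = _as_float_array(self.H, "H")
        _check_nonnegative(self.W, "W")
        _check_nonnegative(self.H, "H")
        if self.W.shape[1] != self.H.shape[0]:
            raise DimensionError(
                f"columns(W)={self.W.shape[1]} must equal rows(H)={self.H.shape[0]}"
            )
        if self.offset is not None:
            self.offset = np.asarray(self.offset, dtype=float).ravel()
            if self.offset.shape[0] != self.W.shape[0]:
                raise DimensionError("offset length must equal the number of features")
            if not np.all(np.isfinite(self.offset)):
                raise DomainError("offset has non-finite entries")
            if self.offset.size and self.offset.min() < 0:
                raise DomainError("offset has negative entries")
        if self.theta is not None and not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError(f"theta must lie in [0, 1], got {self.theta}")
        if self.theta is not None and self.offset is not None:
            raise ConfigurationError("a model cannot have both theta and offset")

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.W.shape[0], self.H.shape[1])

    def copy(self) -> "NMFModel":
        return NMFModel(
            self.W.copy(),
            self.H.copy(),
            None if self.offset is None else self.offset.copy(),
            self.theta,
        )

    def estimate(self) -> np.ndarray:
        return estimate(self)


def estimate(model: NMFModel) -> np.ndarray:
    """The model's reconstruction of the target matrix.

    Plain model: ``W @ H``; non-smooth: ``W @ S(theta) @ H``;
    offset: ``W @ H + offset 1^T``.
    """
    if model.theta is not None:
        S = smoothing_matrix(model.rank, model.theta)
        return model.W @ S @ model.H
    est = model.W @ model.H
    if model.offset is not None:
        est = est + model.offset[:, None]
    return est


def objective(model: NMFModel, X, metric: str = "euclidean") -> float:
    """Approximation loss of ``model`` on ``X``.

    ``euclidean`` is the halved squared Frobenius norm
    ``0.5 * sum((X - Xhat)^2)`` (the residual sum of squares reported by the
    metrics module is the unhalved sum).  ``KL`` is the generalized
    Kullback-Leibler divergence ``sum(X * log(X / Xhat) - X + Xhat)`` with the
    convention ``0 * log 0 = 0``; logarithm arguments carry an epsilon guard.
    """
    Xv = as_target(X).values
    est = estimate(model)
    if est.shape != Xv.shape:
        raise DimensionError(
            f"model estimate shape {est.shape} does not match data shape {Xv.shape}"
        )
    if metric == "euclidean":
        return 0.5 * float(np.sum((Xv - est) ** 2))
    if metric.upper() == "KL":
        # xlogy handles 0*log0; EPS guards the estimate inside the log ratio
        val = np.sum(
            special.xlogy(Xv, Xv) - special.xlogy(Xv, est + EPS) - Xv + est
        )
        return float(val)
    raise ConfigurationError(f"unknown metric {metric!r} (expected 'euclidean' or 'KL')")


def predict_clusters(model: NMFModel, axis: str = "samples") -> np.ndarray:
    """Hard cluster assignments from the dominant metagene.

    Samples are assigned to the metagene that most contributes to their
    expression profile (argmax over each column of ``H``); features to the
    metagene they contribute to most (argmax over each row of ``W``).  Ties
    break toward the lowest metagene index.  Labels are 1-based, in ``1..r``.
    """
    if axis == "samples":
        return np.argmax(model.H, axis=0) + 1
    if axis == "features":
        return np.argmax(model.W, axis=1) + 1
    raise ConfigurationError(f"axis must be 'samples' or 'features', got {axis!r}")


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """One fitted model plus its provenance and objective trajectory."""

    model: NMFModel
    algorithm: str
    seed_method: str
    rng_seed: Optional[int]
    n_iterations: int
    final_objective: float
    objective_track: list[tuple[int, float]]
    metric: str

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.objective_track:
            last = self.objective_track[-1][1]
            if not np.isclose(last, self.final_objective, rtol=1e-12, atol=0.0):
                raise ConfigurationError(
                    "final_objective must equal the last tracked objective value"
                )


@dataclass
class MultiFitResult:
    """A collection of independent fits with their consensus matrix.

    ``consensus`` averages the per-run sample connectivity matrices; its
    entries are empirical co-clustering probabilities.  ``best_index`` points
    to the run with the lowest final objective (ties -> lowest index).
    """

    fits: list[FitResult]
    best_index: int
    consensus: np.ndarray

    def __post_init__(self) -> None:
        self.consensus = np.asarray(self.consensus, dtype=float)
        if not (0 <= self.best_index < len(self.fits)):
            raise ConfigurationError("best_index out of range")

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_index]

    @property
    def nrun(self) -> int:
        return len(self.fits)
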