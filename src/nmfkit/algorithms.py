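"""NMF fitting algorithms, stopping criteria and the multi-run driver.

Five algorithms share one ``fit`` interface:

* ``lee``    -- multiplicative updates minimizing the Frobenius loss;
* ``brunet`` -- multiplicative updates minimizing the Kullback-Leibler loss;
* ``nsnmf``  -- non-smooth NMF: Brunet-style KL updates with the smoothing
  matrix ``S(theta)`` interposed, which trades fit for sparser factors;
* ``offset`` -- KL multiplicative updates for a model with a feature-wise
  constant offset vector;
* ``snmfr``  -- sparse NMF via alternating nonnegativity-constrained least
  squares, with an L1 penalty (``beta``) on the columns of H and a ridge
  penalty (``eta``) on W.

Three stopping criteria apply to the iterative schemes: a fixed iteration
count, invariance of the sample connectivity matrix over a window of
iterations, and stationarity of the objective value.

``multifit`` performs independent runs with per-run seeds spawned
deterministically from a master seed, so results are identical whether runs
execute serially or concurrently, and averages the run connectivity matrices
into a consensus matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import nnls

from .model_core import (
    EPS,
    ConfigurationError,
    DimensionError,
    FitResult,
    MultiFitResult,
    NMFModel,
    NumericalError,
    TargetMatrix,
    as_target,
    estimate,
    logger,
    objective,
    predict_clusters,
    smoothing_matrix,
)
from .metrics import connectivity
from .seeding import SeedSpec, seed_model

MULTIPLICATIVE_METHODS = ("lee", "brunet", "nsnmf", "offset")
METHODS = MULTIPLICATIVE_METHODS + ("snmfr",)

#: Loss metric minimized by each algorithm.
METHOD_METRIC = {
    "lee": "euclidean",
    "brunet": "KL",
    "nsnmf": "KL",
    "offset": "KL",
    "snmfr": "euclidean",
}

DEFAULT_MAX_ITER = 2000  # multiplicative methods
DEFAULT_MAX_ITER_SNMFR = 500  # outer ALS iterations


# ---------------------------------------------------------------------------
# Stopping rules
# ---------------------------------------------------------------------------


@dataclass
class StoppingRule:
    """When to stop an iterative fit.

    ``max_iter`` always caps the iteration count.  ``consensus_invariance``
    additionally stops once the sample connectivity matrix of the current
    model has not changed for ``window`` consecutive iterations (assessed
    every ``check_interval`` iterations, within the run).  ``stationarity``
    stops when the relative change of the objective between checks falls
    below ``tol``.
    """

    kind: str = "consensus_invariance"  # max_iter | consensus_invariance | stationarity
    max_iter: int = DEFAULT_MAX_ITER
    window: int = 40
    tol: float = 1e-6
    check_interval: int = 10

    def __post_init__(self) -> None:
        if self.kind not in {"max_iter", "consensus_invariance", "stationarity"}:
            raise ConfigurationError(f"unknown stopping rule {self.kind!r}")
        if self.max_iter < 1 or self.window < 1 or self.check_interval < 1:
            raise ConfigurationError("max_iter, window and check_interval must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")


def max_iterations(n: int, check_interval: int = 10) -> StoppingRule:
    return StoppingRule(kind="max_iter", max_iter=n, check_interval=check_interval)


def consensus_invariance(
    window: int = 40, max_iter: int = DEFAULT_MAX_ITER, check_interval: int = 10
) -> StoppingRule:
    return StoppingRule(
        kind="consensus_invariance",
        window=window,
        max_iter=max_iter,
        check_interval=check_interval,
    )


def stationarity(
    tol: float = 1e-6, max_iter: int = DEFAULT_MAX_ITER, check_interval: int = 10
) -> StoppingRule:
    return StoppingRule(
        kind="stationarity", tol=tol, max_iter=max_iter, check_interval=check_interval
    )


# ---------------------------------------------------------------------------
# Multiplicative update steps (one iteration each)
# ---------------------------------------------------------------------------


def _check_plain(model: NMFModel, what: str) -> None:
    if model.theta is not None or model.offset is not None:
        raise ConfigurationError(f"{what} requires a plain model (no theta/offset)")


def _check_shapes(model: NMFModel, Xv: np.ndarray) -> None:
    if model.shape != Xv.shape:
        raise DimensionError(
            f"model shape {model.shape} does not match data shape {Xv.shape}"
        )


def update_lee(model: NMFModel, X) -> NMFModel:
    """One Lee-Seung multiplicative step for the Frobenius loss.

    ``H <- H * (W^T X) / (W^T W H)`` then ``W <- W * (X H^T) / (W H H^T)``.
    """
    _check_plain(model, "update_lee")
    Xv = as_target(X).values
    _check_shapes(model, Xv)
    W, H = model.W, model.H
    H = H * (W.T @ Xv) / (W.T @ W @ H + EPS)
    W = W * (Xv @ H.T) / (W @ (H @ H.T) + EPS)
    return NMFModel(W, H)


def update_brunet(model: NMFModel, X) -> NMFModel:
    """One multiplicative step for the Kullback-Leibler loss.

    ``H_au <- H_au * [sum_i W_ia X_iu / (WH)_iu] / sum_k W_ka`` then the
    symmetric update for W.
    """
    _check_plain(model, "update_brunet")
    Xv = as_target(X).values
    _check_shapes(model, Xv)
    W, H = model.W, model.H
    H = H * (W.T @ (Xv / (W @ H + EPS))) / (W.sum(axis=0)[:, None] + EPS)
    W = W * ((Xv / (W @ H + EPS)) @ H.T) / (H.sum(axis=1)[None, :] + EPS)
    return NMFModel(W, H)


def update_nsnmf(model: NMFModel, X) -> NMFModel:
    """One non-smooth NMF step (KL) with the smoothing matrix interposed.

    The H update sees ``W S`` in place of W; the W update sees ``S H`` in
    place of H, where ``S = (1-theta) I + (theta/r) J``.
    """
    if model.theta is None:
        raise ConfigurationError("update_nsnmf requires a model with theta set")
    Xv = as_target(X).values
    _check_shapes(model, Xv)
    W, H = model.W, model.H
    S = smoothing_matrix(model.rank, model.theta)
    Ws = W @ S
    H = H * (Ws.T @ (Xv / (Ws @ H + EPS))) / (Ws.sum(axis=0)[:, None] + EPS)
    Sh = S @ H
    W = W * ((Xv / (W @ Sh + EPS)) @ Sh.T) / (Sh.sum(axis=1)[None, :] + EPS)
    return NMFModel(W, H, theta=model.theta)


def update_offset(model: NMFModel, X) -> NMFModel:
    """One KL multiplicative step for the offset model ``W H + b 1^T``.

    W and H follow the KL updates evaluated against the offset estimate;
    the offset update is ``b_i <- b_i * [sum_u X_iu / est_iu] / p``.
    """
    if model.offset is None:
        raise ConfigurationError("update_offset requires a model with an offset vector")
    Xv = as_target(X).values
    _check_shapes(model, Xv)
    W, H, b = model.W, model.H, model.offset
    p = Xv.shape[1]
    est = W @ H + b[:, None] + EPS
    H = H * (W.T @ (Xv / est)) / (W.sum(axis=0)[:, None] + EPS)
    est = W @ H + b[:, None] + EPS
    W = W * ((Xv / est) @ H.T) / (H.sum(axis=1)[None, :] + EPS)
    est = W @ H + b[:, None] + EPS
    b = b * (Xv / est).sum(axis=1) / p
    return NMFModel(W, H, offset=b)


_UPDATES = {
    "lee": update_lee,
    "brunet": update_brunet,
    "nsnmf": update_nsnmf,
    "offset": update_offset,
}


# ---------------------------------------------------------------------------
# SNMF/R: alternating nonnegativity-constrained least squares
# ---------------------------------------------------------------------------


def _nnls_columns(A: np.ndarray, B: np.ndarray, context: str) -> np.ndarray:
    """Solve min ||A X - B|| with X >= 0, column by column (active set)."""
    out = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        try:
            out[:, j], _ = nnls(A, B[:, j])
        except Exception as exc:  # pragma: no cover - scipy failure path
            raise NumericalError(f"NNLS subproblem failed at {context}, column {j}: {exc}")
    return out


def fit_snmfr(
    X,
    r: int,
    eta: Optional[float] = None,
    beta: float = 0.01,
    stop: Optional[StoppingRule] = None,
    init: Optional[NMFModel] = None,
    rng_seed: Optional[int] = None,
    seed_method: str = "random",
) -> FitResult:
    """Sparse NMF (SNMF/R) by alternating nonnegative least squares.

    Each outer iteration solves the H subproblem
    ``min || [W; sqrt(beta) 1_{1xr}] H - [X; 0] ||, H >= 0``
    (an L1 sparsity penalty on each column of H) and the W subproblem
    ``min || [H^T; sqrt(eta) I_r] W^T - [X^T; 0] ||, W >= 0``
    (a ridge penalty keeping W bounded).  Defaults: ``eta = max(X)^2``,
    ``beta = 0.01``.  The recorded objective/metric is the euclidean data
    loss (penalties excluded).
    """
    Xt = as_target(X)
    Xv = Xt.values
    n, p = Xv.shape
    if r < 1:
        raise ConfigurationError("rank must be >= 1")
    if beta < 0 or (eta is not None and eta < 0):
        raise ConfigurationError("eta and beta must be >= 0")
    if eta is None:
        eta = float(Xv.max()) ** 2
    if stop is None:
        stop = stationarity(max_iter=DEFAULT_MAX_ITER_SNMFR, check_interval=1)
    if init is None:
        init = seed_model(Xt, r, SeedSpec(kind=seed_method, rng_seed=rng_seed))
    W = init.W.copy()
    track: list[tuple[int, float]] = []
    prev_obj = None
    prev_conn = None
    stable_since = None
    H = init.H.copy()
    n_it = 0
    for it in range(1, stop.max_iter + 1):
        n_it = it
        A_h = np.vstack([W, np.sqrt(beta) * np.ones((1, r))])
        B_h = np.vstack([Xv, np.zeros((1, p))])
        H = _nnls_columns(A_h, B_h, f"H update, iteration {it}")
        A_w = np.vstack([H.T, np.sqrt(eta) * np.eye(r)])
        B_w = np.vstack([Xv.T, np.zeros((r, n))])
        W = _nnls_columns(A_w, B_w, f"W update, iteration {it}").T
        obj = 0.5 * float(np.sum((Xv - W @ H) ** 2))
        if not np.isfinite(obj):
            raise NumericalError(f"non-finite objective at SNMF/R iteration {it}")
        if it % stop.check_interval == 0 or it == stop.max_iter:
            track.append((it, obj))
            if stop.kind == "stationarity" and prev_obj is not None:
                if abs(obj - prev_obj) / max(prev_obj, EPS) < stop.tol:
                    break
            prev_obj = obj
            if stop.kind == "consensus_invariance":
                conn = connectivity(np.argmax(H, axis=0))
                if prev_conn is not None and np.array_equal(conn, prev_conn):
                    if stable_since is None:
                        stable_since = it - stop.check_interval
                    if it - stable_since >= stop.window:
                        break
                else:
                    stable_since = None
                prev_conn = conn
    if not track or track[-1][0] != n_it:
        track.append((n_it, obj))
    return FitResult(
        model=NMFModel(W, H),
        algorithm="snmfr",
        seed_method=seed_method,
        rng_seed=rng_seed,
        n_iterations=n_it,
        final_objective=track[-1][1],
        objective_track=track,
        metric="euclidean",
    )


# ---------------------------------------------------------------------------
# Single-interface fit
# ---------------------------------------------------------------------------


def _resolve_seed(seed, rng_seed) -> SeedSpec:
    if isinstance(seed, SeedSpec):
        if rng_seed is not None and seed.rng_seed is None:
            return SeedSpec(seed.kind, rng_seed, seed.model, seed.dense_fill)
        return seed
    if isinstance(seed, NMFModel):
        return SeedSpec(kind="given", model=seed)
    if isinstance(seed, (int, np.integer)):
        return SeedSpec(kind="random", rng_seed=int(seed))
    if isinstance(seed, str):
        return SeedSpec(kind=seed, rng_seed=rng_seed)
    if seed is None:
        return SeedSpec(kind="random", rng_seed=rng_seed)
    raise ConfigurationError(f"cannot interpret seed specification {seed!r}")


def fit(
    X,
    r: int,
    method: str = "brunet",
    seed: Union[str, int, SeedSpec, NMFModel, None] = "random",
    rng_seed: Optional[int] = None,
    stop: Optional[StoppingRule] = None,
    theta: float = 0.5,
    eta: Optional[float] = None,
    beta: float = 0.01,
    track_objective: bool = True,
) -> FitResult:
    """Fit one NMF model: seed, iterate, stop, record.

    The single entry point combining any algorithm with any seeding method.
    ``seed`` accepts a method name (``random``/``nndsvd``/``ica``), a bare
    integer (numeric seed for random initialization), an explicit
    :class:`NMFModel`, or a full :class:`~nmfkit.seeding.SeedSpec`.
    The result is reproducible given (method, seed specification, rng_seed).
    """
    Xt = as_target(X)
    if method not in METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; expected one of {', '.join(METHODS)}"
        )
    n, p = Xt.shape
    if r > min(n, p):
        warnings.warn(
            f"rank {r} exceeds min(n, p) = {min(n, p)}; the factorization will not "
            "reduce dimension",
            stacklevel=2,
        )
    spec = _resolve_seed(seed, rng_seed)
    metric = METHOD_METRIC[method]
    if spec.kind == "nndsvd" and spec.dense_fill is None:
        # multiplicative KL updates are locked at exact zeros
        spec = SeedSpec(
            spec.kind,
            spec.rng_seed,
            spec.model,
            "mean" if metric == "KL" else "none",
        )
    if method == "snmfr":
        if stop is None:
            stop = stationarity(max_iter=DEFAULT_MAX_ITER_SNMFR, check_interval=1)
        init = seed_model(Xt, r, spec)
        res = fit_snmfr(
            Xt, r, eta=eta, beta=beta, stop=stop, init=init,
            rng_seed=spec.rng_seed, seed_method=spec.kind,
        )
        return res
    if stop is None:
        stop = consensus_invariance()
    model = seed_model(Xt, r, spec)
    if method == "nsnmf":
        model = NMFModel(model.W, model.H, theta=theta)
    elif method == "offset":
        model = NMFModel(model.W, model.H, offset=Xt.values.mean(axis=1))
    update = _UPDATES[method]

    track: list[tuple[int, float]] = []
    prev_obj: Optional[float] = None
    stable_since: Optional[int] = None
    prev_conn: Optional[np.ndarray] = None
    n_it = 0
    final_obj = None
    for it in range(1, stop.max_iter + 1):
        n_it = it
        model = update(model, Xt)
        at_check = it % stop.check_interval == 0 or it == stop.max_iter
        if not at_check:
            continue
        obj = objective(model, Xt, metric)
        if not np.isfinite(obj):
            raise NumericalError(f"non-finite objective at iteration {it} ({method})")
        if track_objective:
            track.append((it, obj))
        final_obj = obj
        if stop.kind == "stationarity" and prev_obj is not None:
            if abs(obj - prev_obj) / max(prev_obj, EPS) < stop.tol:
                break
        prev_obj = obj
        if stop.kind == "consensus_invariance":
            conn = connectivity(predict_clusters(model, axis="samples"))
            if prev_conn is not None and np.array_equal(conn, prev_conn):
                if stable_since is None:
                    stable_since = it - stop.check_interval
                if it - stable_since >= stop.window:
                    break
            else:
                stable_since = None
            prev_conn = conn
    if final_obj is None:
        final_obj = objective(model, Xt, metric)
    if not track or track[-1][0] != n_it:
        track.append((n_it, final_obj))
    return FitResult(
        model=model,
        algorithm=method,
        seed_method=spec.kind,
        rng_seed=spec.rng_seed,
        n_iterations=n_it,
        final_objective=final_obj,
        objective_track=track,
        metric=metric,
    )


# ---------------------------------------------------------------------------
# Multiple runs and consensus
# ---------------------------------------------------------------------------


def spawn_run_seeds(master_seed: Optional[int], nrun: int) -> list[int]:
    """Deterministic per-run seeds derived from ``master_seed``.

    Uses ``numpy.random.SeedSequence.spawn`` so the seed of run ``k`` depends
    only on ``(master_seed, k)``: runs may execute in any order, serially or
    concurrently, with identical results.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(nrun)]


def multifit(
    X,
    r: int,
    method: str = "brunet",
    nrun: int = 30,
    master_seed: Optional[int] = None,
    seed: Union[str, SeedSpec] = "random",
    stop: Optional[StoppingRule] = None,
    n_jobs: int = 1,
    **options,
) -> MultiFitResult:
    """``nrun`` independent fits; keep the best, average the connectivities.

    The returned consensus matrix is the mean sample connectivity matrix
    over the (successful) runs -- the empirical probability of each sample
    pair clustering together.  Individual run failures are recorded and
    excluded with a warning; the call fails only if every run fails.
    """
    if nrun < 1:
        raise ConfigurationError("nrun must be >= 1")
    Xt = as_target(X)
    run_seeds = spawn_run_seeds(master_seed, nrun)

    def one(k: int) -> FitResult:
        return fit(Xt, r, method=method, seed=seed, rng_seed=run_seeds[k],
                   stop=stop, **options)

    if n_jobs == 1:
        raw = []
        for k in range(nrun):
            try:
                raw.append(one(k))
            except Exception as exc:
                raw.append(exc)
    else:
        def safe(k):
            try:
                return one(k)
            except Exception as exc:
                return exc
        raw = Parallel(n_jobs=n_jobs)(delayed(safe)(k) for k in range(nrun))

    fits: list[FitResult] = []
    for k, res in enumerate(raw):
        if isinstance(res, Exception):
            warnings.warn(f"run {k + 1} failed and was excluded: {res}", stacklevel=2)
            logger.warning("multifit run %d failed: %s", k + 1, res)
        else:
            fits.append(res)
            logger.info(
                "run %d/%d: %d iterations, final objective %.6g",
                k + 1, nrun, res.n_iterations, res.final_objective,
            )
    if not fits:
        raise NumericalError(f"all {nrun} runs failed")
    objectives = np.array([f.final_objective for f in fits])
    best_index = int(np.argmin(objectives))
    conns = [connectivity(predict_clusters(f.model, axis="samples")) for f in fits]
    consensus = np.mean(conns, axis=0)
    return MultiFitResult(fits=fits, best_index=best_index, consensus=consensus)
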