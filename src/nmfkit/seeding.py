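"""Initialization (seeding) strategies for NMF.

Every strategy returns a valid starting :class:`~nmfkit.model_core.NMFModel`
and can be combined with any fitting algorithm.  Deterministic seeds (NNDSVD,
or random/ICA at a fixed ``rng_seed``) make the whole fit reproducible, so a
single run suffices instead of a multi-start search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .model_core import (
    ConfigurationError,
    DimensionError,
    NMFModel,
    TargetMatrix,
    as_target,
    logger,
)


@dataclass
class SeedSpec:
    """How to build the starting point of a fit.

    ``kind`` is one of ``random`` (i.i.d. uniform entries), ``nndsvd``
    (deterministic SVD-based), ``ica`` (positive part of an independent
    component analysis) or ``given`` (an explicit model, or a bare numeric
    seed which re-routes to ``random``).  ``dense_fill`` controls NNDSVD's
    zero handling: ``mean`` replaces exact zeros by ``mean(X)/100`` so that
    multiplicative (KL) updates are not locked at zero.
    """

    kind: str = "random"
    rng_seed: Optional[int] = None
    model: Optional[NMFModel] = None
    dense_fill: Optional[str] = None  # None | "none" | "mean"

    def __post_init__(self) -> None:
        if self.kind not in {"random", "nndsvd", "ica", "given"}:
            raise ConfigurationError(f"unknown seeding method {self.kind!r}")
        if self.kind == "given" and self.model is None and self.rng_seed is None:
            raise ConfigurationError("kind='given' requires a model or a numeric seed")


def seed_random(X, r: int, rng_seed: Optional[int] = None) -> NMFModel:
    """Classical random initialization.

    Entries of W and H are drawn i.i.d. uniform on ``(0, max(X)]``:
    strictly positive (multiplicative updates cannot revive exact zeros)
    and on the scale of the data.
    """
    Xt = as_target(X)
    if r < 1:
        raise ConfigurationError("rank must be >= 1")
    mx = float(Xt.values.max())
    if mx <= 0:
        mx = 1.0
    rng = np.random.default_rng(rng_seed)
    n, p = Xt.shape
    # 1 - U[0,1) lies in (0, 1]
    W = mx * (1.0 - rng.random((n, r)))
    H = mx * (1.0 - rng.random((r, p)))
    return NMFModel(W, H)


def seed_nndsvd(X, r: int, dense_fill: Optional[str] = None) -> NMFModel:
    """Nonnegative double singular value decomposition (NNDSVD) seed.

    The leading singular triplet provides the first component directly
    (a positive matrix has positive leading singular vectors); each later
    pair ``(u_j, v_j)`` is split into positive and negative parts and the
    section with the larger product of norms is kept, rescaled by its
    singular value.  Fully deterministic; the SVD sign ambiguity is fixed by
    making the largest-magnitude entry of each left singular vector positive.
    """
    Xt = as_target(X)
    n, p = Xt.shape
    if r > min(n, p):
        raise DimensionError(f"rank {r} exceeds min(n, p) = {min(n, p)}")
    U, s, Vt = np.linalg.svd(Xt.values, full_matrices=False)
    W = np.zeros((n, r))
    H = np.zeros((r, p))
    # fix signs: largest-magnitude entry of each u_j positive
    for j in range(r):
        k = np.argmax(np.abs(U[:, j]))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(s[0]) * np.abs(Vt[0, :])
    for j in range(1, r):
        u, v = U[:, j], Vt[j, :]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            norm_prod = n_up * n_vp
            uu = up / n_up if n_up > 0 else up
            vv = vp / n_vp if n_vp > 0 else vp
        else:
            norm_prod = n_un * n_vn
            uu = un / n_un if n_un > 0 else un
            vv = vn / n_vn if n_vn > 0 else vn
        scale = np.sqrt(s[j] * norm_prod)
        W[:, j] = scale * uu
        H[j, :] = scale * vv
    if dense_fill == "mean":
        fill = float(Xt.values.mean()) / 100.0
        W[W == 0] = fill
        H[H == 0] = fill
    return NMFModel(W, H)


def seed_ica(X, r: int, rng_seed: Optional[int] = None) -> NMFModel:
    """Positive part of an independent component analysis of X.

    FastICA (negentropy contrast) decomposes ``X^T ~ sources @ mixing^T``;
    the mixing matrix (features x components) supplies W and the sources
    (samples x components) supply H, each truncated at zero.  ICA leaves the
    sign of every component undetermined; each component pair is flipped so
    that its positive parts carry more mass than its negative parts before
    truncation.  Falls back to :func:`seed_random` (same ``rng_seed``) with a
    warning when ICA does not converge.
    """
    Xt = as_target(X)
    n, p = Xt.shape
    if r > min(n, p):
        raise DimensionError(f"rank {r} exceeds min(n, p) = {min(n, p)}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            ica = FastICA(
                n_components=r, random_state=rng_seed, whiten="unit-variance"
            )
            sources = ica.fit_transform(Xt.values.T)  # p x r
            mixing = ica.mixing_  # n x r
    except (ConvergenceWarning, ValueError) as exc:
        warnings.warn(
            f"ICA seeding did not converge ({exc}); falling back to random seeding",
            stacklevel=2,
        )
        logger.warning("ICA seeding failed, falling back to random: %s", exc)
        return seed_random(Xt, r, rng_seed)
    W = np.empty((n, r))
    H = np.empty((r, p))
    for j in range(r):
        a, srcs = mixing[:, j], sources[:, j]
        mass_pos = np.clip(a, 0, None).sum() * np.clip(srcs, 0, None).sum()
        mass_neg = np.clip(-a, 0, None).sum() * np.clip(-srcs, 0, None).sum()
        if mass_neg > mass_pos:
            a, srcs = -a, -srcs
        W[:, j] = np.clip(a, 0, None)
        H[j, :] = np.clip(srcs, 0, None)
    return NMFModel(W, H)


def seed_model(X, r: int, spec: SeedSpec) -> NMFModel:
    """Dispatch a :class:`SeedSpec` to the matching strategy."""
    if spec.kind == "random":
        return seed_random(X, r, spec.rng_seed)
    if spec.kind == "nndsvd":
        fill = spec.dense_fill if spec.dense_fill not in (None, "none") else None
        return seed_nndsvd(X, r, dense_fill=fill)
    if spec.kind == "ica":
        return seed_ica(X, r, spec.rng_seed)
    # kind == "given": an explicit factorization, or a bare numeric seed,
    # which (mirroring the dual meaning of "seed") routes to seed_random.
    if spec.model is not None:
        Xt = as_target(X)
        if spec.model.shape != Xt.shape or spec.model.rank != r:
            raise DimensionError(
                "explicit seed model has shape "
                f"{spec.model.shape} rank {spec.model.rank}, expected {Xt.shape} rank {r}"
            )
        return spec.model.copy()
    return seed_random(X, r, spec.rng_seed)
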