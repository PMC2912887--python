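"""Synthetic block-structured expression data with known ground truth.

The generator emulates the structure of a multi-class expression study (the
canonical leukemia-subtype setting): ``r`` well-separated sample groups,
each driven by one metagene, observed through ``X = W0 @ H0 + noise``.
Every feature is assigned a dominant metagene (round-robin); dominant
entries of ``W0`` sit around ``signal`` and the rest around ``background``
(default 10:1 contrast).  ``H0`` is a per-group block indicator with the
same multiplicative corruption.  Additive truncated-Gaussian noise is
clipped at zero so the data stay nonnegative.

Defaults mirror the three-class leukemia design: p = 30 samples split
(15, 6, 9) -- the 19/8/11 class proportions of the classic dataset scaled
to 30 -- n = 200 features, signal:background 10:1, noise_sd 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model_core import ConfigurationError, TargetMatrix


@dataclass
class SyntheticSpec:
    """Parameters of the block-structured generator (all expression units arbitrary)."""

    n: int = 200
    p: int = 30
    r: int = 3
    group_sizes: Optional[Sequence[int]] = None
    signal: float = 1.0
    background: float = 0.1
    noise_sd: float = 0.1
    offset_row: Optional[float] = None
    subtype_pair: Optional[tuple[int, int]] = None
    subtype_level: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            self.group_sizes = _default_groups(self.p, self.r)
        self.group_sizes = [int(g) for g in self.group_sizes]
        if len(self.group_sizes) != self.r:
            raise ConfigurationError("group_sizes must have length r")
        if sum(self.group_sizes) != self.p:
            raise ConfigurationError(
                f"group sizes {self.group_sizes} do not sum to p = {self.p}"
            )
        if any(g < 1 for g in self.group_sizes):
            raise ConfigurationError("every group must contain at least one sample")
        if not self.signal > self.background >= 0:
            raise ConfigurationError("need signal > background >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.subtype_pair is not None:
            a, b = self.subtype_pair
            if not (1 <= a <= self.r and 1 <= b <= self.r and a != b):
                raise ConfigurationError(
                    f"subtype_pair must name two distinct groups in 1..{self.r}"
                )
            if not self.background < self.subtype_level * self.signal < self.signal:
                raise ConfigurationError(
                    "subtype_level * signal must lie between background and signal"
                )


def _default_groups(p: int, r: int) -> list[int]:
    """Unequal group sizes echoing the 19/8/11 three-class proportions.

    For r != 3 (or tiny p) groups are split as evenly as possible.
    """
    if r == 3 and p >= 6:
        props = np.array([19, 8, 11], dtype=float) / 38.0
        sizes = np.maximum(1, np.floor(props * p).astype(int))
        while sizes.sum() < p:
            sizes[np.argmax(props * p - sizes)] += 1
        while sizes.sum() > p:
            sizes[np.argmax(sizes)] -= 1
        return sizes.tolist()
    base = p // r
    sizes = [base] * r
    for i in range(p - base * r):
        sizes[i] += 1
    return sizes


@dataclass
class SyntheticData:
    """Generated data plus its ground truth."""

    X: TargetMatrix
    W0: np.ndarray
    H0: np.ndarray
    labels: list[str]
    spec: SyntheticSpec


def _corrupt(rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
    """Truncated-normal corruption: sd = 0.1 * mean, clipped at zero."""
    return np.clip(rng.normal(mean, 0.1 * mean), 0.0, None)


def make_synthetic(spec: Optional[SyntheticSpec] = None, **overrides) -> SyntheticData:
    """Generate one block-structured dataset, fully determined by ``rng_seed``.

    Keyword overrides are applied on top of ``spec`` (or the defaults), e.g.
    ``make_synthetic(noise_sd=0, rng_seed=7)``.
    """
    if spec is None:
        spec = SyntheticSpec(**overrides)
    elif overrides:
        from dataclasses import asdict

        params = asdict(spec)
        params.update(overrides)
        spec = SyntheticSpec(**params)
    rng = np.random.default_rng(spec.rng_seed)

    dominant = np.arange(spec.n) % spec.r  # round-robin metagene assignment
    means_W = np.full((spec.n, spec.r), float(spec.background))
    means_W[np.arange(spec.n), dominant] = float(spec.signal)
    if spec.subtype_pair is not None:
        # hierarchical class structure (two groups are subtypes of a common
        # parent, as with the ALL-B/ALL-T leukemia subtypes): each subtype
        # group also expresses the other's marker features at an
        # intermediate level, so a 2-way split merging them dominates
        a, b = spec.subtype_pair[0] - 1, spec.subtype_pair[1] - 1
        shared = float(spec.subtype_level * spec.signal)
        means_W[dominant == a, b] = shared
        means_W[dominant == b, a] = shared
    W0 = _corrupt(rng, means_W)

    group_of = np.repeat(np.arange(spec.r), spec.group_sizes)
    means_H = np.zeros((spec.r, spec.p))
    means_H[group_of, np.arange(spec.p)] = 1.0
    H0 = _corrupt(rng, means_H)

    X = W0 @ H0
    if spec.offset_row is not None:
        X = X + float(spec.offset_row)
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    X = np.clip(X, 0.0, None)

    labels = [f"g{g + 1}" for g in group_of]
    target = TargetMatrix(X, class_labels=labels)
    return SyntheticData(X=target, W0=W0, H0=H0, labels=labels, spec=spec)


def make_marker_matrix(
    n: int = 1000,
    r: int = 3,
    marker_fraction: float = 0.3,
    dominance: float = 10.0,
    jitter: float = 0.05,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Basis matrix with planted metagene-specific rows, for selection tests.

    A fraction of rows is metagene-specific (one entry ``dominance`` times
    the others, round-robin over metagenes); the remaining rows are uniform.
    All entries carry small multiplicative jitter.  Returns ``(W, planted)``
    where ``planted`` is the boolean mask of marker rows.
    """
    rng = np.random.default_rng(rng_seed)
    n_markers = int(round(marker_fraction * n))
    planted = np.zeros(n, dtype=bool)
    planted[:n_markers] = True
    W = np.ones((n, r))
    W[np.arange(n_markers), np.arange(n_markers) % r] = dominance
    W = W * np.clip(rng.normal(1.0, jitter, size=W.shape), 0.0, None)
    perm = rng.permutation(n)
    return W[perm], planted[perm]
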