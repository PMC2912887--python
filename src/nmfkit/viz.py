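"""Pre-configured heatmaps and residual plots for NMF results.

Four displays: the mixture-coefficient heatmap (columns scaled to sum to
one, ordered by cluster), the basis heatmap (rows scaled to sum to one,
ordered by average-linkage euclidean clustering, optionally restricted to
selected features), the consensus heatmap (rows and columns ordered by the
same dendrogram, colour scale anchored at 0 and 1) and the residual track
plot (each run's objective trajectory normalized by its own maximum).

Every function returns the plotted (scaled, ordered) data alongside the
image path, and writes it as a sidecar TSV, so downstream checks can assert
on data rather than pixels.  Factor heatmaps run yellow (low) to red (high);
the consensus map runs dark blue (0) to red (1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .model_core import EPS, FitResult, NMFModel, predict_clusters

FACTOR_CMAP = "YlOrRd"  # yellow -> red
CONSENSUS_CMAP = "RdBu_r"  # dark blue -> red


@dataclass
class PlotArtifact:
    """The data behind a plot, plus where the image/sidecar were written."""

    data: pd.DataFrame
    path: Optional[Path]
    annotations: dict


def _hclust_order(points: np.ndarray) -> np.ndarray:
    """Leaf order of average-linkage clustering on euclidean distances."""
    m = points.shape[0]
    if m < 3:
        return np.arange(m)
    return leaves_list(average(pdist(points)))


def _save_heatmap(
    data: pd.DataFrame,
    path: Optional[Union[str, Path]],
    cmap: str,
    title: str,
    vmin=None,
    vmax=None,
    annotations: Optional[dict] = None,
) -> Optional[Path]:
    if path is None:
        return None
    path = Path(path)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * data.shape[1] + 2), max(3.0, min(10.0, 0.02 * data.shape[0] + 3)))
    )
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax,
                   interpolation="nearest")
    ax.set_title(title)
    if data.shape[1] <= 60:
        ax.set_xticks(range(data.shape[1]))
        ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    if data.shape[0] <= 60:
        ax.set_yticks(range(data.shape[0]))
        ax.set_yticklabels(data.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    if annotations:
        txt = "; ".join(f"{k}: {' '.join(map(str, v))}" for k, v in annotations.items())
        fig.text(0.01, 0.01, txt[:300], fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    data.to_csv(path.with_suffix(".tsv"), sep="\t", float_format="%.12g")
    return path


def coefmap(
    H,
    sample_ids: Optional[Sequence[str]] = None,
    labels: Optional[Sequence] = None,
    clusters: Optional[Sequence[int]] = None,
    path: Optional[Union[str, Path]] = None,
) -> PlotArtifact:
    """Heatmap of the mixture coefficients H.

    Columns are scaled to sum to one (relative metagene contribution per
    sample) and ordered so samples of the same predicted cluster are
    contiguous; class labels, when given, ride along as an annotation track.
    """
    H = np.asarray(H, dtype=float)
    r, p = H.shape
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(p)]
    if clusters is None:
        clusters = np.argmax(H, axis=0) + 1
    clusters = np.asarray(clusters)
    sums = H.sum(axis=0)
    scaled = H / np.where(sums > 0, sums, 1.0)
    order = np.argsort(clusters, kind="stable")
    data = pd.DataFrame(
        scaled[:, order],
        index=[f"metagene{q + 1}" for q in range(r)],
        columns=[sample_ids[j] for j in order],
    )
    annotations = {"cluster": [int(clusters[j]) for j in order]}
    if labels is not None:
        annotations["class"] = [labels[j] for j in order]
    out = _save_heatmap(data, path, FACTOR_CMAP, "Metagene expression profiles (H)",
                        annotations=annotations)
    return PlotArtifact(data=data, path=out, annotations=annotations)


def basismap(
    W,
    feature_ids: Optional[Sequence[str]] = None,
    selection=None,
    path: Optional[Union[str, Path]] = None,
) -> PlotArtifact:
    """Heatmap of the basis matrix W.

    Optionally restricted to a feature selection; rows are scaled to sum to
    one and ordered by average-linkage euclidean clustering of the scaled
    rows.  An empty selection falls back to the full matrix with a warning.
    """
    W = np.asarray(W, dtype=float)
    n, r = W.shape
    if feature_ids is None:
        feature_ids = [f"f{i + 1}" for i in range(n)]
    rows = np.arange(n)
    if selection is not None:
        idx = np.asarray(selection.selected if hasattr(selection, "selected") else selection)
        if idx.size == 0:
            warnings.warn("empty feature selection; plotting the full basis matrix",
                          stacklevel=2)
        else:
            rows = idx
    sub = W[rows]
    sums = sub.sum(axis=1)
    scaled = sub / np.where(sums > 0, sums, 1.0)[:, None]
    order = _hclust_order(scaled)
    data = pd.DataFrame(
        scaled[order],
        index=[feature_ids[i] for i in rows[order]],
        columns=[f"metagene{q + 1}" for q in range(r)],
    )
    out = _save_heatmap(data, path, FACTOR_CMAP, "Basis components (W)")
    return PlotArtifact(data=data, path=out, annotations={})


def consensusmap(
    consensus,
    sample_ids: Optional[Sequence[str]] = None,
    path: Optional[Union[str, Path]] = None,
) -> PlotArtifact:
    """Heatmap of the consensus matrix, values plotted unmodified in [0, 1].

    Rows and columns share one ordering: average-linkage clustering of the
    euclidean distances between consensus rows.
    """
    C = np.asarray(consensus, dtype=float)
    p = C.shape[0]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(p)]
    order = _hclust_order(C)
    names = [sample_ids[j] for j in order]
    data = pd.DataFrame(C[np.ix_(order, order)], index=names, columns=names)
    out = _save_heatmap(data, path, CONSENSUS_CMAP, "Consensus matrix",
                        vmin=0.0, vmax=1.0)
    return PlotArtifact(data=data, path=out, annotations={"order": list(order)})


def residual_plot(
    fits: Sequence[FitResult],
    path: Optional[Union[str, Path]] = None,
) -> PlotArtifact:
    """Objective trajectories, each normalized by its own maximum.

    One curve per fit; x is the iteration number, so curves end at each
    run's stopping iteration.
    """
    records = []
    for k, f in enumerate(fits):
        if not f.objective_track:
            continue
        its, objs = zip(*f.objective_track)
        peak = max(objs)
        peak = peak if peak > 0 else 1.0
        name = f"{f.algorithm}#{k + 1}"
        for it, obj in zip(its, objs):
            records.append({"track": name, "iteration": it, "objective": obj / peak})
    data = pd.DataFrame.from_records(records, columns=["track", "iteration", "objective"])
    out = None
    if path is not None:
        out = Path(path)
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, grp in data.groupby("track", sort=False):
            ax.plot(grp["iteration"], grp["objective"], label=name)
        ax.set_xlabel("iteration")
        ax.set_ylabel("objective / max(objective)")
        ax.set_title("Residual trajectories")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out, dpi=120)
        plt.close(fig)
        data.to_csv(out.with_suffix(".tsv"), sep="\t", index=False, float_format="%.12g")
    return PlotArtifact(data=data, path=out, annotations={})
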