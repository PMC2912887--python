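"""Reading and writing expression matrices and fit results.

Supports GCT v1.2 and plain delimited text (TSV/CSV, features as rows,
header row of sample ids).  Also provides the coefficient-of-variation gene
filter commonly used to reduce a full array to its most variable genes, and
deterministic writers for fitted factorizations (W/H tables, consensus,
objective track, JSON run report).  All writers use fixed 12-significant-
digit float formatting and fixed key order, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model_core import (
    DataError,
    DimensionError,
    FitResult,
    MultiFitResult,
    TargetMatrix,
)

_FLOAT_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".gct":
        return "gct"
    if suffix == ".csv":
        return "csv"
    return "tsv"


# ---------------------------------------------------------------------------
# Matrix readers / writers
# ---------------------------------------------------------------------------


def read_matrix(
    path: Union[str, Path],
    format: Optional[str] = None,
    class_labels=None,
) -> TargetMatrix:
    """Read a feature x sample expression matrix.

    GCT: version line ``#1.2``, a dimension line, then a header with
    ``Name``/``Description`` columns followed by sample ids.  TSV/CSV: header
    row of sample ids, first column feature ids.  Negative or missing values
    are rejected with the offending cell named.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "gct":
        df, descriptions = _read_gct(path)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise DataError(f"cannot parse {path} as {fmt}: {exc}")
        descriptions = None
    else:
        raise DataError(f"unknown matrix format {format!r}")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise DataError(f"{path}: non-numeric entries in the data block")
    bad = np.argwhere(~np.isfinite(values.astype(float)))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"{path}: missing/non-finite value for feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise DataError(
            f"{path}: negative value {values[i, j]!r} for feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    target = TargetMatrix(
        values.astype(float),
        feature_ids=[str(x) for x in df.index],
        sample_ids=[str(x) for x in df.columns],
        class_labels=class_labels,
    )
    target.descriptions = descriptions  # GCT Description column, if any
    return target


def _read_gct(path: Path) -> tuple[pd.DataFrame, list[str]]:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise DataError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise DataError(f"{path}: malformed GCT dimension line")
        try:
            n, p = int(dims[0]), int(dims[1])
        except ValueError:
            raise DataError(f"{path}: non-integer GCT dimensions {dims!r}")
        df = pd.read_csv(fh, sep="\t")
    if df.shape[1] != p + 2:
        raise DataError(
            f"{path}: GCT header declares {p} samples but data has "
            f"{df.shape[1] - 2} sample columns"
        )
    if df.shape[0] != n:
        raise DataError(
            f"{path}: GCT header declares {n} rows but data has {df.shape[0]}"
        )
    descriptions = [str(d) for d in df.iloc[:, 1]]
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    return df, descriptions


def read_labels(path: Union[str, Path]) -> list[str]:
    """Read one class label per line (or a sample<TAB>label two-column file)."""
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            labels.append(parts[-1])
    if not labels:
        raise DataError(f"{path}: no labels found")
    return labels


def write_matrix(X: TargetMatrix, path: Union[str, Path], format: Optional[str] = None) -> Path:
    """Write a target matrix as GCT v1.2 or delimited text (deterministic)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    n, p = X.shape
    if fmt == "gct":
        descriptions = getattr(X, "descriptions", None) or [""] * n
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n}\t{p}\n")
            fh.write("Name\tDescription\t" + "\t".join(X.sample_ids) + "\n")
            for i in range(n):
                row = "\t".join(_fmt(v) for v in X.values[i])
                fh.write(f"{X.feature_ids[i]}\t{descriptions[i]}\t{row}\n")
    else:
        sep = "\t" if fmt == "tsv" else ","
        with open(path, "w") as fh:
            fh.write("feature_id" + sep + sep.join(X.sample_ids) + "\n")
            for i in range(n):
                row = sep.join(_fmt(v) for v in X.values[i])
                fh.write(f"{X.feature_ids[i]}{sep}{row}\n")
    return path


def write_labels(labels, path: Union[str, Path], sample_ids=None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for j, lab in enumerate(labels):
            if sample_ids is not None:
                fh.write(f"{sample_ids[j]}\t{lab}\n")
            else:
                fh.write(f"{lab}\n")
    return path


# ---------------------------------------------------------------------------
# CV filter
# ---------------------------------------------------------------------------


def cv_filter(X: TargetMatrix, k: int) -> TargetMatrix:
    """Keep the k most variable features by coefficient of variation.

    CV is sd/mean per feature row, with the sample (n-1) standard deviation;
    rows with mean 0 get CV 0.  Ties break toward the earlier row, and the
    surviving rows keep their original order.
    """
    n = X.n_features
    if not 1 <= k <= n:
        raise DimensionError(f"k must lie in [1, {n}], got {k}")
    means = X.values.mean(axis=1)
    sds = X.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, 0.0)
    # stable sort on -cv keeps original order among ties
    order = np.argsort(-cv, kind="stable")[:k]
    keep = np.sort(order)
    out = TargetMatrix(
        X.values[keep],
        feature_ids=[X.feature_ids[i] for i in keep],
        sample_ids=X.sample_ids,
        class_labels=X.class_labels,
    )
    descr = getattr(X, "descriptions", None)
    if descr is not None:
        out.descriptions = [descr[i] for i in keep]
    return out


# ---------------------------------------------------------------------------
# Fit writers
# ---------------------------------------------------------------------------


def _write_table(path: Path, header: list[str], index: list[str], values: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join([""] + header) + "\n")
        for i, name in enumerate(index):
            fh.write(name + "\t" + "\t".join(_fmt(v) for v in values[i]) + "\n")


def write_fit(
    result: Union[FitResult, MultiFitResult],
    out_dir: Union[str, Path],
    X: Optional[TargetMatrix] = None,
    extra_report: Optional[dict] = None,
) -> dict[str, Path]:
    """Write a fit (or multi-run fit) as a deterministic file set.

    Produces ``W.tsv`` (features x metagenes), ``H.tsv`` (metagenes x
    samples), ``objective_track.tsv``, ``report.json`` and -- for multi-run
    results -- ``consensus.tsv``.  The report records algorithm, seeding,
    every RNG seed, iteration counts and final objectives, which is enough
    to re-run the fit bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    if isinstance(result, MultiFitResult):
        best = result.best
        fits = result.fits
        consensus = result.consensus
    else:
        best = result
        fits = [result]
        consensus = None

    model = best.model
    n, p = model.shape
    r = model.rank
    feature_ids = X.feature_ids if X is not None else [f"f{i + 1}" for i in range(n)]
    sample_ids = X.sample_ids if X is not None else [f"s{j + 1}" for j in range(p)]
    metagenes = [f"metagene{q + 1}" for q in range(r)]

    files["W"] = out_dir / "W.tsv"
    _write_table(files["W"], metagenes, list(feature_ids), model.W)
    files["H"] = out_dir / "H.tsv"
    _write_table(files["H"], list(sample_ids), metagenes, model.H)
    if model.offset is not None:
        files["offset"] = out_dir / "offset.tsv"
        _write_table(files["offset"], ["offset"], list(feature_ids), model.offset[:, None])
    if consensus is not None:
        files["consensus"] = out_dir / "consensus.tsv"
        _write_table(files["consensus"], list(sample_ids), list(sample_ids), consensus)

    files["objective_track"] = out_dir / "objective_track.tsv"
    with open(files["objective_track"], "w") as fh:
        fh.write("run\titeration\tobjective\n")
        for k, f in enumerate(fits):
            for it, obj in f.objective_track:
                fh.write(f"{k + 1}\t{it}\t{_fmt(obj)}\n")

    report = {
        "algorithm": best.algorithm,
        "seed_method": best.seed_method,
        "metric": best.metric,
        "rank": r,
        "nrun": len(fits),
        "best_index": int(result.best_index) if isinstance(result, MultiFitResult) else 0,
        "rng_seeds": [f.rng_seed for f in fits],
        "n_iterations": [f.n_iterations for f in fits],
        "final_objective": [f.final_objective for f in fits],
        "theta": model.theta,
        "has_offset": model.offset is not None,
    }
    if extra_report:
        report.update(extra_report)
    files["report"] = out_dir / "report.json"
    with open(files["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files


def write_feature_selection(selection, path: Union[str, Path]) -> Path:
    """Two-column table (feature_id, score) with the threshold in a header comment."""
    path = Path(path)
    ids = selection.feature_ids
    with open(path, "w") as fh:
        fh.write(
            f"# threshold_s={_fmt(selection.threshold_s)} "
            f"mu={_fmt(selection.mu)} sigma={_fmt(selection.sigma)} "
            f"n_selected={selection.n_selected}\n"
        )
        fh.write("feature_id\tscore\n")
        for i in selection.selected:
            name = ids[i] if ids is not None else f"f{i + 1}"
            fh.write(f"{name}\t{_fmt(selection.scores[i])}\n")
    return path
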