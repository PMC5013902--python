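"""Matrix input, expression preprocessing and result output.

Matrices are observation-major: rows are cells/mutations/samples, columns
are features.  Delimited text (TSV/CSV, optional leading row-name column)
and MatrixMarket coordinate files (with optional ``.rows``/``.cols``
sidecar name files) are supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "RunConfig",
    "read_matrix",
    "preprocess_expression",
    "write_labels",
    "run_densitycut",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class RunConfig:
    """Parameters of one end-to-end clustering run."""

    input_path: str
    out_prefix: str
    fmt: str = "tsv"  # tsv | csv | mtx | graph
    k: int | str = "auto"
    alpha: float = 0.9
    n_levels: int = 100
    adjust: bool = True
    metric: str = "euclidean"
    seed: int = 0
    transpose: bool = False
    min_cells: int | None = None
    log2_transform: bool = False
    extra: dict = field(default_factory=dict)


def _read_delimited(path, sep: str):
    try:
        df = pd.read_csv(path, sep=sep, header=None, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    ids = None
    first_row_header = not pd.api.types.is_numeric_dtype(df.iloc[0]) and df.shape[0] > 1 and (
        df.iloc[0].apply(lambda v: isinstance(v, str)).all()
    )
    if first_row_header:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] > 1 and df[0].dtype == object:
        try:
            pd.to_numeric(df[0])
        except (ValueError, TypeError):
            ids = df[0].astype(str).to_numpy()
            df = df.drop(columns=0)
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=np.float64)
    except (ValueError, TypeError):
        for i, row in df.iterrows():
            for cell in row:
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at data line {i + 1}"
                    ) from None
        raise FormatError(f"{path}: non-numeric data")  # pragma: no cover
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite values in matrix")
    return values, ids


def read_matrix(path, fmt: str = "tsv"):
    """Read a numeric point matrix; returns ``(values, row_ids_or_None)``.

    ``fmt`` is one of tsv, csv, mtx.  MatrixMarket input is densified;
    an optional ``<path>.rows`` sidecar supplies row names.
    """
    path = Path(path)
    if fmt == "tsv":
        return _read_delimited(path, "\t")
    if fmt == "csv":
        return _read_delimited(path, ",")
    if fmt == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if sp.issparse(mat) else mat, dtype=np.float64
        )
        sidecar = path.with_suffix(path.suffix + ".rows")
        ids = None
        if sidecar.exists():
            ids = np.array(sidecar.read_text().split())
            if len(ids) != values.shape[0]:
                raise FormatError(
                    f"{sidecar}: {len(ids)} row names for {values.shape[0]} rows"
                )
        return values, ids
    raise FormatError(f"unknown matrix format {fmt!r}")


def preprocess_expression(
    matrix: np.ndarray,
    min_cells: int = 5,
    transform: bool = True,
    expressed_threshold: float = 1.0,
    strict: bool = True,
):
    """Filter rarely-expressed genes and log-transform expression values.

    A gene (column) is considered expressed in a cell when its value is at
    least ``expressed_threshold`` (RPKM/FPKM >= 1 by convention).  Genes
    expressed in more than ``min_cells`` cells are kept (``strict=False``
    relaxes the rule to at-least).  When ``transform`` is set, the kept
    values are mapped through log2(x + 1), so zeros stay zero.

    Returns ``(filtered_matrix, kept_column_indices)``.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    expressed_in = np.count_nonzero(matrix >= expressed_threshold, axis=0)
    kept = np.flatnonzero(
        expressed_in > min_cells if strict else expressed_in >= min_cells
    )
    out = matrix[:, kept]
    if transform:
        out = np.log2(out + 1.0)
    return out, kept


def write_labels(path, labels: np.ndarray, ids=None, header: dict | None = None):
    """Write per-node labels as TSV, 1-based cluster ids, 0 for outliers."""
    labels = np.asarray(labels)
    with open(path, "w") as fh:
        if header:
            for key, val in header.items():
                fh.write(f"# {key}: {val}\n")
        fh.write("node_id\tcluster\n")
        for i, lab in enumerate(labels):
            name = ids[i] if ids is not None else i
            fh.write(f"{name}\t{int(lab) + 1}\n")


def run_densitycut(config: RunConfig):
    """Compose the full pipeline for one configuration and write results.

    Emits ``<prefix>.labels.tsv``, ``<prefix>.merge_tree.json``,
    ``<prefix>.frequency.tsv`` and a run log; returns the fitted estimator.
    """
    from .cluster import DensityCut
    from .graph import read_edge_list

    ids = None
    if config.fmt == "graph":
        data = read_edge_list(config.input_path)
    else:
        values, ids = read_matrix(config.input_path, config.fmt)
        if config.transpose:
            values = values.T
            ids = None
        if config.min_cells is not None or config.log2_transform:
            values, _ = preprocess_expression(
                values,
                min_cells=config.min_cells if config.min_cells is not None else 5,
                transform=config.log2_transform,
            )
        data = values

    model = DensityCut(
        n_neighbors=config.k,
        alpha=config.alpha,
        n_levels=config.n_levels,
        adjust=config.adjust,
        metric=config.metric,
    ).fit(data)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tree = model.merge_tree_
    write_labels(
        f"{prefix}.labels.tsv",
        model.labels_,
        ids=ids,
        header={
            "k": model.graph_.k,
            "alpha": config.alpha,
            "levels": config.n_levels,
            "adjust": config.adjust,
            "metric": config.metric,
            "seed": config.seed,
            "n_clusters": model.n_clusters_,
            "iterations_used": model.n_iter_,
        },
    )
    with open(f"{prefix}.merge_tree.json", "w") as fh:
        json.dump(
            {
                "levels": tree.levels.tolist(),
                "counts_per_level": tree.counts_per_level.tolist(),
                "merges": [
                    {
                        "threshold": None if np.isnan(t) else t,
                        "tree_a": int(a),
                        "tree_b": int(b),
                        "saliency": s,
                    }
                    for t, a, b, s in tree.merges
                ],
                "selected_count": tree.selected_count,
                "modes": model.forest_.modes.tolist(),
            },
            fh,
            indent=1,
        )
    with open(f"{prefix}.frequency.tsv", "w") as fh:
        fh.write("cluster_count\tfrequency\n")
        for count in sorted(tree.frequency):
            fh.write(f"{count}\t{tree.frequency[count]}\n")
    with open(f"{prefix}.log", "w") as fh:
        fh.write(json.dumps(asdict(config), default=str) + "\n")
        fh.write(
            f"n={len(model.labels_)} k={model.graph_.k} "
            f"iterations={model.n_iter_} selected={model.n_clusters_}\n"
        )
    return model
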