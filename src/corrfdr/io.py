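"""Delimited-text I/O for matrices, labels, p-value lists and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidArgumentError
from .screening import FeatureMatrix, FdrScreenResults

__all__ = [
    "read_matrix",
    "read_labels",
    "read_pvalue_list",
    "read_simulation_config",
    "write_results",
]


def _sep(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_labels(path) -> pd.Series:
    """Sample-id -> {0,1} label map from a two-column delimited file.

    A header row is optional and detected by a non 0/1 second column.
    """
    frame = pd.read_csv(path, sep=_sep(path), header=None, dtype=str,
                        comment="#", skip_blank_lines=True)
    if frame.shape[1] != 2:
        raise InvalidArgumentError(
            f"labels file {path} must have exactly 2 columns (sample id, 0/1)"
        )
    if frame.iloc[0, 1] not in ("0", "1"):
        frame = frame.iloc[1:]
    labels = frame.set_index(0)[1]
    bad = labels[~labels.isin(("0", "1"))]
    if len(bad):
        raise InvalidArgumentError(
            f"label for sample {bad.index[0]!r} is {bad.iloc[0]!r}, expected 0 or 1"
        )
    return labels.astype(int)


def read_matrix(path, labels_path, transpose: bool = False) -> FeatureMatrix:
    """Load a delimited matrix plus label file into a FeatureMatrix.

    The matrix file has feature ids in the first row and sample ids in
    the first column (pass ``transpose=True`` for features x samples
    layouts, e.g. expression matrices with genes as rows).  Every
    sample in the labels file must appear in the matrix and vice versa.
    """
    frame = pd.read_csv(path, sep=_sep(path), index_col=0)
    if transpose:
        frame = frame.T
    non_numeric = frame.columns[
        [not np.issubdtype(dt, np.number) for dt in frame.dtypes]
    ]
    if len(non_numeric):
        raise InvalidArgumentError(
            f"column {non_numeric[0]!r} of {path} contains non-numeric cells"
        )
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any()][0]
        row = frame.index[frame[col].isna()][0]
        raise InvalidArgumentError(
            f"missing value in {path} at sample {row!r}, feature {col!r}"
        )
    labels = read_labels(labels_path)
    extra = [s for s in labels.index if s not in set(map(str, frame.index))]
    if extra:
        raise InvalidArgumentError(
            f"labels file names sample {extra[0]!r} absent from the matrix"
        )
    missing = [s for s in map(str, frame.index) if s not in labels.index]
    if missing:
        raise InvalidArgumentError(f"no group label for sample {missing[0]!r}")
    group = labels.reindex(map(str, frame.index)).to_numpy()
    return FeatureMatrix(frame.to_numpy(dtype=float), group,
                         frame.columns.to_numpy(), frame.index.to_numpy())


def read_pvalue_list(path) -> np.ndarray:
    """One-column (optionally headed) list of numbers, e.g. sorted p-values."""
    frame = pd.read_csv(path, sep=_sep(path), header=None, comment="#", dtype=str)
    col = frame[0]
    try:
        float(col.iloc[0])
    except ValueError:  # first row is a header
        col = col.iloc[1:]
    return pd.to_numeric(col).to_numpy(dtype=float)


def read_simulation_config(path) -> dict:
    """YAML or JSON mapping of SimulationConfig field names."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidArgumentError(f"config {path} must be a mapping")
    return data


def write_results(results: FdrScreenResults, path, pretty: bool = False) -> None:
    """Write the rank-ordered results table as TSV.

    Full precision by default; ``pretty=True`` formats numeric columns
    to 4 decimals for display parity with published tables.
    """
    table = results.table()
    fmt = "%.4f" if pretty else "%.17g"  # %.17g round-trips doubles exactly
    table.to_csv(path, sep="\t", index=False, float_format=fmt)
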