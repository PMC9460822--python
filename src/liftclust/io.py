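"""CSV schemas and validated round-trip readers/writers.

All tables are comma-delimited UTF-8 with a header row; the trial key is
(participant_id, trial_index); floats are written with 6 significant digits.
Schema violations raise :class:`SchemaError` naming the offending column or
line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "FEATURE_COLUMNS",
    "TRIAL_COLUMNS",
    "TRACE_COLUMNS",
    "read_features",
    "write_features",
    "read_labels",
    "write_labels",
    "read_traces",
    "write_traces",
    "write_merge_tree",
    "read_merge_tree",
    "write_curve",
]

FLOAT_FORMAT = "%.6g"
KEY_COLUMNS = ["participant_id", "trial_index"]
FEATURE_COLUMNS = KEY_COLUMNS + ["trunk_rom", "hip_rom", "knee_rom"]
TRIAL_COLUMNS = KEY_COLUMNS + ["true_cluster", "pseq", "pain"]
TRACE_COLUMNS = KEY_COLUMNS + ["joint", "sample_index", "angle_deg"]


class SchemaError(ValueError):
    """A table failed schema validation."""


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_no_nan(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: one for the header row, one for 0-based indexing
            raise SchemaError(f"{path}: NaN in column {col!r} at line {bad[0] + 2}")


def _check_unique_key(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise SchemaError(f"{path}: duplicate trial key at line {line}")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, FEATURE_COLUMNS, path)
    _check_no_nan(df, FEATURE_COLUMNS, path)
    _check_unique_key(df, path)
    for col in ("trunk_rom", "hip_rom", "knee_rom"):
        if (df[col] < 0).any():
            line = int(df.index[df[col] < 0][0]) + 2
            raise SchemaError(f"{path}: negative {col} at line {line}")
    return df[FEATURE_COLUMNS + [c for c in df.columns if c not in FEATURE_COLUMNS]]


def write_features(df: pd.DataFrame, path) -> None:
    _check_columns(df, FEATURE_COLUMNS, path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, KEY_COLUMNS, path)
    label_cols = [c for c in df.columns if c not in KEY_COLUMNS]
    if not label_cols:
        raise SchemaError(f"{path}: no label columns beyond the trial key")
    _check_no_nan(df, KEY_COLUMNS + label_cols, path)
    _check_unique_key(df, path)
    for col in label_cols:
        values = df[col]
        if not np.issubdtype(values.dtype, np.integer):
            raise SchemaError(f"{path}: label column {col!r} must be integer")
    return df


def write_labels(df: pd.DataFrame, path) -> None:
    _check_columns(df, KEY_COLUMNS, path)
    df.to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, TRACE_COLUMNS, path)
    _check_no_nan(df, TRACE_COLUMNS, path)
    return df


def write_traces(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRACE_COLUMNS, path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_merge_tree(tree, path) -> None:
    """Plain-text merge table: step, node_a, node_b, height, size."""
    merges = tree.merges
    df = pd.DataFrame(
        {
            "step": np.arange(merges.shape[0]),
            "node_a": merges[:, 0].astype(int),
            "node_b": merges[:, 1].astype(int),
            "height": merges[:, 2],
            "size": merges[:, 3].astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_merge_tree(path):
    from .cluster import MergeTree

    df = pd.read_csv(path)
    _check_columns(df, ["step", "node_a", "node_b", "height", "size"], path)
    merges = df[["node_a", "node_b", "height", "size"]].to_numpy(dtype=float)
    return MergeTree(merges=merges)


def write_curve(curve, path) -> None:
    """Selection-curve CSV: k, wss, silhouette."""
    pd.DataFrame(
        {"k": curve.k_values, "wss": curve.wss, "silhouette": curve.silhouette}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)
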