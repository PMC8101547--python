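"""CSV dataset readers/writers, hierarchy edge lists, and model persistence.

Datasets travel as a single UTF-8 CSV with a header row: feature columns plus
named target columns.  A row whose target cells are ALL empty is unlabeled;
partially empty targets are rejected.  Sparse features use a triplet CSV
(row, col, value) with targets in a companion CSV.  Hierarchies are TSV edge
lists (``parent<TAB>child``, ``#`` comments allowed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import HierarchySpec, SemiDataset, Task, encode_targets
from .ensemble import Ensemble
from .tree import Tree

__all__ = ["DataFileSpec", "read_dataset", "write_dataset", "read_hierarchy",
           "write_hierarchy", "load_model", "save_model"]


@dataclass
class DataFileSpec:
    """Where a dataset lives on disk and which columns are targets."""

    features_csv: str | Path
    target_columns: Sequence[str]
    hierarchy_path: str | Path | None = None
    sparse: bool = False
    targets_csv: str | Path | None = None  # required in sparse mode


def read_hierarchy(path, labels: Sequence[str] | None = None) -> HierarchySpec:
    """Parse a ``parent<TAB>child`` edge list into a label hierarchy.

    ``labels``, when given, fixes the label universe (and order); edge labels
    must be a subset of it.  Without it, labels are the sorted union of the
    edge endpoints.
    """
    edges = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'parent<TAB>child'")
        parent, child = (x.strip() for x in parts)
        if parent == child:
            raise ValueError(
                f"{path}:{lineno}: self-edge {parent!r} forms a cycle")
        edges.append((parent, child))
        seen.update((parent, child))
    if labels is None:
        labels = sorted(seen)
    else:
        unknown = seen - set(labels)
        if unknown:
            raise ValueError(
                f"hierarchy label {sorted(unknown)[0]!r} is not a target column")
    return HierarchySpec(list(labels), edges)


def write_hierarchy(hier: HierarchySpec, path) -> None:
    lines = [f"{p}\t{c}" for p, c in hier.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _parse_raw_targets(df_targets: pd.DataFrame, task: Task):
    """Per-task raw values from labeled target cells."""
    if task in (Task.STR, Task.MTR):
        return df_targets.astype(float).to_numpy()
    if task in (Task.BC, Task.MCC):
        if df_targets.shape[1] != 1:
            # accept already-encoded indicator columns
            return df_targets.astype(float).to_numpy()
        return df_targets.iloc[:, 0].astype(str).to_numpy()
    return df_targets.astype(float).to_numpy()  # MLC/HMLC indicators


def read_dataset(spec: DataFileSpec, task: Task) -> tuple[SemiDataset, list[str]]:
    """Read a dataset from disk; returns ``(dataset, label_order)``.

    The dataset is reordered labeled-first; the original row order is kept in
    ``dataset.orig_index``.
    """
    task = Task(task)
    hier = None
    if spec.sparse:
        if spec.targets_csv is None:
            raise ValueError("sparse mode requires a separate targets CSV")
        trip = pd.read_csv(spec.features_csv)
        rows = trip.iloc[:, 0].astype(int).to_numpy()
        cols = trip.iloc[:, 1].astype(int).to_numpy()
        vals = trip.iloc[:, 2].astype(float).to_numpy()
        df_t = pd.read_csv(spec.targets_csv, dtype=str, keep_default_na=False)
        n = len(df_t)
        D = int(cols.max()) + 1 if cols.size else 1
        X = sp.csr_matrix((vals, (rows, cols)), shape=(n, D))
        df_targets = df_t[list(spec.target_columns)]
    else:
        df = pd.read_csv(spec.features_csv, dtype=str, keep_default_na=False)
        missing = [c for c in spec.target_columns if c not in df.columns]
        if missing:
            raise ValueError(f"target column {missing[0]!r} not found")
        feat_cols = [c for c in df.columns if c not in set(spec.target_columns)]
        try:
            X = df[feat_cols].astype(float).to_numpy()
        except ValueError as err:
            for c in feat_cols:
                for i, v in enumerate(df[c]):
                    try:
                        float(v)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric feature cell at row {i}, "
                            f"column {c!r}: {v!r}") from err
            raise
        df_targets = df[list(spec.target_columns)]
    empty = df_targets.apply(lambda s: s.str.strip() == "").to_numpy()
    all_empty = empty.all(axis=1)
    some_empty = empty.any(axis=1) & ~all_empty
    if some_empty.any():
        row = int(np.flatnonzero(some_empty)[0])
        raise ValueError(
            f"row {row}: targets are partially missing; a row must be fully "
            "labeled or fully unlabeled")
    labeled = np.flatnonzero(~all_empty)
    unlabeled = np.flatnonzero(all_empty)
    if labeled.size == 0:
        raise ValueError("no labeled rows in the dataset")
    order = np.concatenate([labeled, unlabeled])
    if task is Task.HMLC:
        if spec.hierarchy_path is None:
            raise ValueError("HMLC requires a hierarchy file")
        hier = read_hierarchy(spec.hierarchy_path, list(spec.target_columns))
        # reorder target columns to the hierarchy's order
        df_targets = df_targets[hier.labels]
    raw = _parse_raw_targets(df_targets.iloc[labeled], task)
    if task in (Task.MLC, Task.HMLC):
        label_names = list(df_targets.columns)
        Y = np.asarray(raw, dtype=float)
        if task is Task.HMLC:
            hier.check_consistent(Y)
    elif task in (Task.BC, Task.MCC) and raw.ndim == 1:
        Y, label_names = encode_targets(raw, task)
    else:
        Y = np.asarray(raw, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        label_names = list(df_targets.columns)
    ds = SemiDataset(X[order], Y, task, hier, orig_index=order)
    return ds, label_names


def write_dataset(ds: SemiDataset, path, label_order: Sequence[str] | None = None,
                  hierarchy_path=None) -> None:
    """Write a dataset to the CSV format read_dataset understands."""
    if ds.is_sparse:
        raise ValueError("write_dataset only supports dense features")
    label_order = list(label_order) if label_order is not None else [
        f"y{j}" for j in range(ds.T)]
    n, D = ds.X.shape
    df = pd.DataFrame(ds.X, columns=[f"x{j}" for j in range(D)])
    for j, name in enumerate(label_order):
        col = [""] * n
        for i in range(ds.L):
            v = ds.Y[i, j]
            col[i] = repr(int(v)) if float(v).is_integer() else repr(float(v))
        df[name] = col
    df.to_csv(path, index=False)
    if ds.hierarchy is not None and hierarchy_path is not None:
        write_hierarchy(ds.hierarchy, hierarchy_path)


def save_model(model: Tree | Ensemble, path) -> None:
    model.save(path)


def load_model(path) -> Tree | Ensemble:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("model") == "ensemble":
        return Ensemble.from_dict(doc)
    return Tree.from_dict(doc)
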