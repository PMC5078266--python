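"""Subject-level connectivity matrices and their on-disk formats.

A connectivity matrix is the pipeline's atomic input: a symmetric,
zero-diagonal, nonnegative ``q x q`` array of streamline counts between
gray-matter parcels, together with parcel labels.  Matrices are read from
square delimited text (CSV/TSV, optional header row of labels) or
MatrixMarket coordinate files; cohorts are described by a manifest CSV
with columns ``subject_id, group, path``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse

GROUP_LABELS = ("HC", "CIS", "RR", "SP", "PP")


class InvalidMatrixError(ValueError):
    """Raised when an array violates the connectivity-matrix contract."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Weighted adjacency of one subject's structural connectome.

    Parameters
    ----------
    values : ndarray of shape (q, q)
        Nonnegative symmetric streamline counts with a zero diagonal.
    node_labels : list of str
        Parcel names, one per node.  Defaults to ``n001 ... n<q>``.
    """

    values: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidMatrixError(f"matrix must be square, got shape {v.shape}")
        if v.shape[0] < 2:
            raise InvalidMatrixError("need at least 2 nodes")
        bad = np.argwhere(v != v.T)
        if bad.size:
            i, j = bad[0]
            raise InvalidMatrixError(
                f"matrix not symmetric: entry ({i}, {j}) != ({j}, {i})"
            )
        neg = np.argwhere(v < 0)
        if neg.size:
            i, j = neg[0]
            raise InvalidMatrixError(f"negative weight at ({i}, {j})")
        if np.any(np.diag(v) != 0):
            i = int(np.nonzero(np.diag(v))[0][0])
            raise InvalidMatrixError(f"nonzero diagonal at ({i}, {i})")
        object.__setattr__(self, "values", v)
        labels = tuple(self.node_labels) or tuple(
            f"n{i + 1:03d}" for i in range(v.shape[0])
        )
        if len(labels) != v.shape[0]:
            raise InvalidMatrixError(
                f"{len(labels)} labels for {v.shape[0]} nodes"
            )
        object.__setattr__(self, "node_labels", labels)

    @property
    def q(self) -> int:
        return self.values.shape[0]

    def positive_pairs(self) -> int:
        """Number of upper-triangle entries with strictly positive weight."""
        iu = np.triu_indices(self.q, k=1)
        return int(np.count_nonzero(self.values[iu] > 0))


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort row: a subject id, its group label, and its matrix."""

    subject_id: str
    group: str
    matrix: ConnectivityMatrix

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {GROUP_LABELS}"
            )


def read_matrix(path: str | Path, delimiter: str | None = None) -> ConnectivityMatrix:
    """Read a connectivity matrix from delimited text or MatrixMarket.

    Delimited files may carry a first header row of node labels; the
    format is sniffed from the extension (``.mtx`` -> MatrixMarket) and,
    for text, from the first line.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        m = np.asarray(m, dtype=float)
        m = np.maximum(m, m.T)  # coordinate files may carry one triangle
        np.fill_diagonal(m, 0.0)
        return ConnectivityMatrix(m)
    text = path.read_text().strip().splitlines()
    if not text:
        raise InvalidMatrixError(f"{path}: empty file")
    delim = delimiter or ("\t" if "\t" in text[0] else ",")
    first = text[0].split(delim)
    labels: tuple[str, ...] = ()
    try:
        float(first[0])
        rows = text
    except ValueError:
        labels = tuple(s.strip() for s in first)
        rows = text[1:]
    values = np.array([[float(x) for x in r.split(delim)] for r in rows])
    return ConnectivityMatrix(values, labels)


def write_matrix(m: ConnectivityMatrix, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(m.node_labels) + "\n")
        for row in m.values:
            fh.write(delimiter.join(format(x, "g") for x in row) + "\n")


def write_binary_adjacency(
    adjacency: np.ndarray, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a 0/1 adjacency matrix as delimited text."""
    np.savetxt(path, np.asarray(adjacency, dtype=int), fmt="%d", delimiter=delimiter)


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Load a cohort from a manifest CSV (subject_id, group, path).

    Matrix paths are resolved relative to the manifest's directory.
    Every file is checked for readability before any matrix is parsed so
    a broken cohort fails fast with a per-file message.
    """
    path = Path(path)
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    missing = [
        r["path"] for r in rows if not (path.parent / r["path"]).is_file()
    ]
    if missing:
        raise FileNotFoundError(f"manifest {path}: unreadable inputs {missing}")
    return [
        SubjectRecord(r["subject_id"], r["group"], read_matrix(path.parent / r["path"]))
        for r in rows
    ]


def write_manifest(records: Sequence[SubjectRecord], directory: str | Path) -> Path:
    """Write one TSV matrix per subject plus a manifest CSV; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group", "path"])
        for rec in records:
            fname = f"{rec.subject_id}.tsv"
            write_matrix(rec.matrix, directory / fname)
            w.writerow([rec.subject_id, rec.group, fname])
    return manifest
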