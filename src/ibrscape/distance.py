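"""Labelled symmetric distance matrices and lower-triangle unfolding."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINDS = ("euclidean", "flat_resistance", "resistance", "fst")


@dataclass
class DistanceMatrix:
    """A labelled symmetric matrix tagged by what it measures.

    ``kind`` is one of ``euclidean``, ``flat_resistance``, ``resistance``
    or ``fst``.  The diagonal is zero; off-diagonal entries may be
    ``inf`` for disconnected pairs of a resistance matrix.  F_ST matrices
    may hold slightly negative estimates, so nonnegativity is not
    enforced for ``kind='fst'``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "euclidean"

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape must match number of labels")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite], self.values.T[finite], rtol=0, atol=1e-12
        ):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path, kind: str = "euclidean") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), kind=kind)


def pair_order(labels: list[str]) -> list[tuple[str, str]]:
    """The fixed (i < j) pair order used by :func:`unfold`."""
    return [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def unfold(matrix: DistanceMatrix, labels: list[str] | None = None) -> np.ndarray:
    """Lower-triangle entries as a vector in fixed (i < j) label order.

    ``labels`` fixes the order shared across all matrices of a fit; the
    matrix must contain exactly those labels.
    """
    if labels is None:
        labels = matrix.labels
    if set(labels) != set(matrix.labels) or len(labels) != len(matrix.labels):
        raise ValueError("label mismatch between matrices")
    idx = [matrix.labels.index(l) for l in labels]
    vals = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(labels), k=1)
    return vals[iu]


def euclidean_matrix(xy: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances from a projected (x, y) site table."""
    coords = xy[["x", "y"]].to_numpy()
    diff = coords[:, None, :] - coords[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(list(xy.index.astype(str)), vals, kind="euclidean")
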