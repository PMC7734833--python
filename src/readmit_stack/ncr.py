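"""Neighborhood cleaning rule (NCR) under-sampling.

NCR reduces class imbalance by deleting majority-class training rows that sit
in minority neighbourhoods, using 3-nearest-neighbour rules in the normalized
encoded feature space:

1. find the k = 3 nearest neighbours of every training row;
2. a majority row is marked if at least two of its three nearest neighbours
   are minority rows (it lies inside minority territory);
3. for every minority row, its majority-class nearest neighbours are marked
   (they crowd the minority sample).

All marks are computed against the original, unmodified dataset and applied
simultaneously — the outcome does not depend on row iteration order. Only
majority rows are ever removed, so the imbalance ratio can only decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .preprocess import DesignMatrix

__all__ = ["LabeledDataset", "find_k_nearest", "ncr_undersample"]


@dataclass
class LabeledDataset:
    """A design matrix annotated with minority/majority row partitions."""

    matrix: DesignMatrix
    minority_idx: np.ndarray
    majority_idx: np.ndarray

    @classmethod
    def from_matrix(cls, matrix: DesignMatrix) -> "LabeledDataset":
        labels = matrix.labels
        return cls(
            matrix,
            minority_idx=np.where(labels == 1)[0],
            majority_idx=np.where(labels == 0)[0],
        )

    def __post_init__(self) -> None:
        self.minority_idx = np.asarray(self.minority_idx, dtype=int)
        self.majority_idx = np.asarray(self.majority_idx, dtype=int)
        n = self.matrix.n_rows
        combined = np.sort(np.concatenate([self.minority_idx, self.majority_idx]))
        if not np.array_equal(combined, np.arange(n)):
            raise ValueError("minority and majority subsets must partition the rows")

    @property
    def n_rows(self) -> int:
        return self.matrix.n_rows

    @property
    def imbalance_ratio(self) -> float:
        """Majority count / minority count (written 1:x in the literature)."""
        if len(self.minority_idx) == 0:
            raise ValueError("imbalance ratio undefined without minority rows")
        return len(self.majority_idx) / len(self.minority_idx)

    @property
    def X(self) -> np.ndarray:
        return self.matrix.values

    @property
    def y(self) -> np.ndarray:
        return self.matrix.labels


def _neighbor_order(X: np.ndarray, row: int) -> np.ndarray:
    """All other rows sorted by (Euclidean distance to ``row``, row index)."""
    d = cdist(X[row : row + 1], X)[0]
    d[row] = np.inf  # exclude self
    order = np.lexsort((np.arange(len(d)), d))
    return order[: len(d) - 1]


def find_k_nearest(dataset: LabeledDataset, row: int, k: int = 3) -> np.ndarray:
    """The ``k`` nearest rows to ``row`` (self excluded), Euclidean distance,
    ties broken by ascending row index."""
    if k >= dataset.n_rows:
        raise ValueError(
            f"k={k} must be smaller than the number of rows ({dataset.n_rows})"
        )
    return _neighbor_order(dataset.X, row)[:k]


def ncr_undersample(
    dataset: LabeledDataset, k: int = 3
) -> tuple[LabeledDataset, int]:
    """Apply the neighborhood cleaning rule once; returns (reduced, removed).

    Both rules are evaluated on the original dataset and the union of marked
    majority rows is removed in one shot. Minority rows are never removed. A
    second application may remove further rows; this function performs the
    single pass the procedure prescribes.
    """
    if len(dataset.minority_idx) == 0 or len(dataset.majority_idx) == 0:
        raise ValueError("both class subsets must be non-empty")
    if dataset.n_rows < 4:
        raise ValueError("NCR needs at least 4 rows")
    if k >= dataset.n_rows:
        raise ValueError("k must be smaller than the number of rows")

    X, y = dataset.X, dataset.y
    n = dataset.n_rows
    # One neighbour computation shared by both rules.
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        neighbors[i] = _neighbor_order(X, i)[:k]

    marked = np.zeros(n, dtype=bool)
    minority = y == 1
    for i in range(n):
        if minority[i]:
            # Minority rule: majority neighbours crowding a minority sample.
            nbrs = neighbors[i]
            marked[nbrs[~minority[nbrs]]] = True
        else:
            # Majority rule: majority sample inside minority territory
            # (at least 2 of 3 neighbours minority at the default k=3; a
            # strict neighbour majority for other k).
            if minority[neighbors[i]].sum() >= k // 2 + 1:
                marked[i] = True

    # Only majority rows are removable by construction of both rules, but
    # enforce the guarantee explicitly.
    marked &= ~minority
    keep = np.where(~marked)[0]
    removed = int(marked.sum())
    reduced = LabeledDataset.from_matrix(dataset.matrix.subset_rows(keep))
    return reduced, removed
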