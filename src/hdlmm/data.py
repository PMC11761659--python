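"""Clustered data container for mixed-effects regression.

Observations are grouped into clusters; within a cluster, responses share a
draw of the random-effect vector. The container validates shapes, maps
arbitrary group labels to contiguous integer codes, and records which
fixed-effect columns are exempt from penalization (by convention the
intercept and every column that also carries a random effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusteredData"]


@dataclass(frozen=True)
class ClusteredData:
    """Design matrices, response and cluster structure for one data set.

    Parameters
    ----------
    X : ndarray, shape (N, p)
        Fixed-effect design matrix.
    Z : ndarray, shape (N, q)
        Random-effect design matrix; columns are typically a subset of the
        columns of ``X`` (plus an intercept).
    y : ndarray, shape (N,)
        Response vector.
    groups : array-like, shape (N,)
        Cluster membership labels (any hashable type); mapped to contiguous
        integer codes internally, original labels retained.
    nonpen : frozenset of int
        0-based indices of unpenalized columns of ``X``.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    nonpen: frozenset = frozenset()
    group_labels: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        N, p = X.shape
        if Z.shape[0] != N:
            raise ValueError(f"Z has {Z.shape[0]} rows, expected {N}")
        if y.shape[0] != N:
            raise ValueError(f"y has length {y.shape[0]}, expected {N}")
        if Z.shape[1] < 1:
            raise ValueError("Z must have at least one column (q >= 1)")
        for name, arr in (("X", X), ("Z", Z), ("y", y)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")
        raw = np.asarray(self.groups)
        if raw.shape[0] != N:
            raise ValueError(f"groups has length {raw.shape[0]}, expected {N}")
        codes, labels = pd.factorize(raw)
        if len(labels) < 2:
            raise ValueError("need at least 2 clusters for variance estimation")
        nonpen = frozenset(int(j) for j in self.nonpen)
        if nonpen and (min(nonpen) < 0 or max(nonpen) >= p):
            raise ValueError("nonpen indices out of range")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "groups", codes.astype(np.intp))
        object.__setattr__(self, "group_labels", np.asarray(labels))
        object.__setattr__(self, "nonpen", nonpen)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def cluster_indices(self) -> list[np.ndarray]:
        """Row-index arrays, one per cluster, in code order."""
        idx = getattr(self, "_cluster_indices", None)
        if idx is None:
            idx = [np.flatnonzero(self.groups == i) for i in range(self.n_groups)]
            object.__setattr__(self, "_cluster_indices", idx)
        return idx

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.array([len(ix) for ix in self.cluster_indices])

    def penalized_mask(self) -> np.ndarray:
        """Boolean mask over columns of X, True where the coefficient is penalized."""
        mask = np.ones(self.n_fixed, dtype=bool)
        mask[list(self.nonpen)] = False
        return mask
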