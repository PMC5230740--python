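"""Row-standardised spatial neighbour weights over grid cells.

Neighbourhoods are defined by a centroid-distance threshold; at the default
150 km on the 96.486-km grid this captures exactly the eight surrounding
cells of an interior cell (queen contiguity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree


class SpatialWeights:
    """Symmetric binary contiguity, row-standardised on demand.

    Parameters
    ----------
    binary : scipy.sparse matrix
        Symmetric 0/1 adjacency without self-neighbours.
    ids : array-like, optional
        External labels for the units (defaults to 0..n-1).
    """

    def __init__(self, binary, ids=None, threshold_km: float | None = None):
        binary = sparse.csr_matrix(binary)
        if (binary != binary.T).nnz != 0:
            raise ValueError("binary adjacency must be symmetric")
        if binary.diagonal().any():
            raise ValueError("self-neighbours are not allowed")
        self.binary = binary
        self.n = binary.shape[0]
        self.ids = np.arange(self.n) if ids is None else np.asarray(ids)
        self.threshold_km = threshold_km
        self.degrees = np.asarray(binary.sum(axis=1)).ravel()
        self.isolated = np.flatnonzero(self.degrees == 0)
        self._eigs = None
        self._W = None

    @classmethod
    def from_points(cls, xy, ids=None, threshold_km: float = 150.0):
        """Neighbours = units whose centroids lie within ``threshold_km``."""
        xy = np.asarray(xy, dtype=float)
        n = len(xy)
        pairs = cKDTree(xy).query_pairs(r=threshold_km, output_type="ndarray")
        if len(pairs):
            i = np.concatenate([pairs[:, 0], pairs[:, 1]])
            j = np.concatenate([pairs[:, 1], pairs[:, 0]])
            data = np.ones(len(i))
        else:
            i = j = data = np.array([])
        binary = sparse.coo_matrix((data, (i, j)), shape=(n, n))
        return cls(binary, ids=ids, threshold_km=threshold_km)

    @classmethod
    def from_table(cls, table: pd.DataFrame, threshold_km: float = 150.0):
        xy = table[["x_km", "y_km"]].to_numpy()
        return cls.from_points(xy, ids=table["cell_id"].to_numpy(),
                               threshold_km=threshold_km)

    @property
    def W(self):
        """Row-standardised weights (rows of isolated units stay zero)."""
        if self._W is None:
            inv = np.zeros(self.n)
            nz = self.degrees > 0
            inv[nz] = 1.0 / self.degrees[nz]
            self._W = sparse.diags(inv) @ self.binary
            self._W = sparse.csr_matrix(self._W)
        return self._W

    @property
    def s0(self) -> float:
        """Sum of all row-standardised weights."""
        return float(self.n - len(self.isolated))

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the row-standardised W.

        W = D^-1 B is similar to the symmetric D^-1/2 B D^-1/2, so its
        spectrum is real; the symmetric form is what is diagonalised.
        Cached, since the spectrum is the expensive part of repeated SAR
        likelihood evaluations on the same neighbour structure.
        """
        if self._eigs is None:
            d = self.degrees.astype(float)
            inv_sqrt = np.zeros(self.n)
            nz = d > 0
            inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
            S = sparse.diags(inv_sqrt) @ self.binary @ sparse.diags(inv_sqrt)
            self._eigs = np.linalg.eigvalsh(S.toarray())
        return self._eigs

    def subset(self, index) -> "SpatialWeights":
        """Weights restricted to a subset of units (re-standardised)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sub = self.binary[index][:, index]
        return SpatialWeights(sub, ids=self.ids[index],
                              threshold_km=self.threshold_km)

    def neighbors(self, i: int) -> np.ndarray:
        return self.binary.indices[self.binary.indptr[i]:self.binary.indptr[i + 1]]

    # -- serialisation -------------------------------------------------------
    def to_triplets(self) -> pd.DataFrame:
        coo = sparse.coo_matrix(self.W)
        return pd.DataFrame({"i": self.ids[coo.row], "j": self.ids[coo.col],
                             "w": coo.data})

    def to_csv(self, path):
        self.to_triplets().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ids=None):
        df = pd.read_csv(path)
        if ids is None:
            ids = np.unique(np.concatenate([df["i"], df["j"]]))
        pos = {v: k for k, v in enumerate(ids)}
        i = df["i"].map(pos).to_numpy()
        j = df["j"].map(pos).to_numpy()
        binary = sparse.coo_matrix(
            (np.ones(len(df)), (i, j)), shape=(len(ids), len(ids)))
        binary = binary.maximum(binary.T)
        return cls(binary, ids=ids)


def build_weights(table_or_xy, threshold_km: float = 150.0) -> SpatialWeights:
    """Build row-standardised weights from a grid table or coordinate array."""
    if isinstance(table_or_xy, pd.DataFrame):
        return SpatialWeights.from_table(table_or_xy, threshold_km=threshold_km)
    return SpatialWeights.from_points(table_or_xy, threshold_km=threshold_km)
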