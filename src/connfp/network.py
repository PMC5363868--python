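"""Per-subject functional network construction.

Pipeline: Pearson correlation of ROI time series -> Fisher r-to-z -> fixed
sparsity binarization (keep the k strongest edges, k = round(s * R(R-1)/2))
-> cohort-wide search for the minimum sparsity at which every subject's
network is a single connected component.  Networks are undirected and
unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .preprocess import RoiTimeSeries


@dataclass
class CorrMatrix:
    values: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if np.abs(v - v.T).max() > 1e-12:
            raise ValueError("correlation matrix must be symmetric")
        self.values = v


@dataclass
class ZMatrix:
    """Fisher-transformed correlation matrix; diagonal stored as 0."""

    values: np.ndarray
    roi_names: list[str]

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    adjacency: np.ndarray  # {0,1}, symmetric, zero diagonal
    sparsity: float
    roi_names: list[str]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n_nodes, 1)
        keep = self.adjacency[iu, ju] > 0
        return [(self.roi_names[i], self.roi_names[j])
                for i, j in zip(iu[keep], ju[keep])]


@dataclass(frozen=True)
class SparsityGrid:
    lo: float = 0.01
    hi: float = 0.50
    step: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.lo <= self.hi <= 1:
            raise ValueError("need 0 < lo <= hi <= 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    def values(self) -> np.ndarray:
        n = int(np.floor((self.hi - self.lo) / self.step + 1e-9)) + 1
        return np.round(self.lo + self.step * np.arange(n), 10)


def correlation_matrix(ts: RoiTimeSeries) -> CorrMatrix:
    """Pearson correlation between all ROI pairs."""
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = data.std(axis=0)
    if (sd == 0).any():
        bad = [ts.roi_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI(s): {', '.join(bad)}")
    c = np.corrcoef(data, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CorrMatrix(c, list(ts.roi_names))


def fisher_z(c: CorrMatrix) -> ZMatrix:
    """Variance-stabilizing atanh transform; |r| clipped just below 1."""
    r = c.values.copy()
    np.fill_diagonal(r, 0.0)
    limit = 1.0 - 1e-7
    if np.abs(r).max() > limit:
        warnings.warn("correlations with |r| >= 1 clipped before atanh")
        r = np.clip(r, -limit, limit)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ZMatrix(z, list(c.roi_names))


def _ranked_edges(z: ZMatrix, ranking: str = "signed"):
    """Upper-triangle pairs sorted by edge strength (desc), ties by (i, j)."""
    iu, ju = np.triu_indices(z.n_rois, 1)
    vals = z.values[iu, ju]
    if ranking == "absolute":
        vals = np.abs(vals)
    elif ranking != "signed":
        raise ValueError(f"unknown ranking {ranking!r}")
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def binarize_at_sparsity(z: ZMatrix, s: float,
                         ranking: str = "signed") -> BinaryNetwork:
    """Keep the round(s * R(R-1)/2) strongest edges.

    ``ranking='signed'`` ranks by z directly (strong negative correlations
    are excluded); ``'absolute'`` ranks by |z|.  Ties broken toward the
    lexicographically smaller (i, j) pair, so results are deterministic.
    """
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    r = z.n_rois
    n_pairs = r * (r - 1) // 2
    k = int(round(s * n_pairs))
    iu, ju = _ranked_edges(z, ranking)
    adj = np.zeros((r, r), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, float(s), list(z.roi_names))


def is_connected(net: BinaryNetwork) -> bool:
    """True iff the network forms a single connected component."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    n_comp, _ = connected_components(csr_matrix(net.adjacency), directed=False)
    return n_comp == 1


def n_components(net: BinaryNetwork) -> int:
    n_comp, _ = connected_components(csr_matrix(net.adjacency), directed=False)
    return int(n_comp)


def _min_connected_sparsity(z: ZMatrix, grid_values: np.ndarray,
                            ranking: str) -> float | None:
    """Smallest grid sparsity at which this subject's network is connected."""
    r = z.n_rois
    n_pairs = r * (r - 1) // 2
    iu, ju = _ranked_edges(z, ranking)
    for s in grid_values:
        k = int(round(s * n_pairs))
        adj = csr_matrix((np.ones(k), (iu[:k], ju[:k])), shape=(r, r))
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1:
            return float(s)
    return None


def minimum_common_sparsity(zs: list[ZMatrix], grid: SparsityGrid = SparsityGrid(),
                            ranking: str = "signed") -> float:
    """Smallest grid sparsity at which EVERY subject's network is connected.

    Because edges are added in a fixed rank order, per-subject connectivity
    is monotone in sparsity, so the answer is the maximum over subjects of
    each subject's own minimum connected sparsity.
    """
    if not zs:
        raise ValueError("need at least one z-matrix")
    r = zs[0].n_rois
    if any(z.n_rois != r for z in zs):
        raise ValueError("all z-matrices must have the same ROI count")
    grid_values = grid.values()
    minima = [_min_connected_sparsity(z, grid_values, ranking) for z in zs]
    if any(m is None for m in minima):
        bad = [f"subject {i}: disconnected up to sparsity {grid.hi}"
               for i, m in enumerate(minima) if m is None]
        raise ValueError("no grid sparsity connects all subjects; " + "; ".join(bad))
    return float(max(minima))
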