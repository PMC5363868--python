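"""Eigenvector centrality on binarized functional networks.

A node's eigenvector centrality is proportional to the sum of the
centralities of its neighbours; for a connected undirected graph this is the
(strictly positive) Perron eigenvector of the adjacency matrix. Centrality of
a disconnected graph is refused: the Perron vector is not well defined across
components, and the in-pipeline sparsity search guarantees connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BinaryNetwork, n_components

#: dense eigendecomposition below this size, power iteration above
_DENSE_LIMIT = 512


@dataclass
class CentralityVector:
    values: np.ndarray
    principal_eigenvalue: float
    normalization: str = "unit_euclidean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _power_iteration(adj: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    x = np.full(adj.shape[0], 1.0 / np.sqrt(adj.shape[0]))
    lam = 0.0
    for _ in range(max_iter):
        y = adj @ x
        lam = float(np.linalg.norm(y))
        if lam == 0:
            return x, 0.0
        y /= lam
        if np.abs(y - x).max() < tol:
            return y, lam
        x = y
    return x, lam


def eigenvector_centrality(net: BinaryNetwork,
                           normalization: str = "unit_euclidean") -> CentralityVector:
    """Principal eigenvector of the adjacency matrix, sign-fixed non-negative.

    ``normalization`` is ``'unit_euclidean'`` (default) or ``'max_one'``
    (largest entry rescaled to 1).
    """
    if normalization not in ("unit_euclidean", "max_one"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ncomp = n_components(net)
    if ncomp != 1:
        raise ValueError(f"network has {ncomp} connected components; eigenvector "
                         "centrality requires a single component")
    adj = net.adjacency.astype(float)
    if net.n_nodes <= _DENSE_LIMIT:
        w, v = np.linalg.eigh(adj)
        lam = float(w[-1])
        x = v[:, -1]
    else:
        x, lam = _power_iteration(adj)
    if x.sum() < 0:
        x = -x
    # Perron vector of a connected graph is positive; clamp numerical dust.
    if x.min() < -1e-8:
        raise ArithmeticError("principal eigenvector has a significantly "
                              "negative entry; eigensolver failure")
    x = np.clip(x, 0.0, None)
    x = x / np.linalg.norm(x)
    residual = np.abs(adj @ x - lam * x).max()
    if residual > 1e-8:
        raise ArithmeticError(f"eigenpair residual {residual:.2e} exceeds 1e-8")
    if normalization == "max_one":
        x = x / x.max()
    return CentralityVector(x, lam, normalization)


def subject_centrality_features(networks: list[BinaryNetwork],
                                target_roi_indices: list[int],
                                normalization: str = "unit_euclidean") -> np.ndarray:
    """subjects x target-ROIs matrix of per-subject eigenvector centrality."""
    if not networks:
        raise ValueError("need at least one network")
    r = networks[0].n_nodes
    names = networks[0].roi_names
    for net in networks:
        if net.n_nodes != r or net.roi_names != names:
            raise ValueError("all networks must share nodes and ROI names")
    rows = [eigenvector_centrality(net, normalization).values[target_roi_indices]
            for net in networks]
    return np.vstack(rows)
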