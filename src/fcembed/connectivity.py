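"""Pearson functional connectivity and walk-ready weighted graphs.

For ROI time series ``L_i`` and ``L_j`` the functional connectivity is the
Pearson correlation ``PC_ij = cov(L_i, L_j) / (sigma_i sigma_j)``; a
130 x 116 ROI matrix yields a 116 x 116 symmetric, unit-diagonal
correlation matrix.  Random-walk transition probabilities require
non-negative edge weights, so signed correlations pass through an explicit
``negative_policy``: ``absolute`` keeps anticorrelation topology via
``|PC|`` (default), ``clip`` discards negative edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import TimeSeriesMatrix

__all__ = ["ConnectivityMatrix", "WeightedGraph", "pearson_connectivity",
           "to_weighted_graph", "save_connectivity", "load_connectivity",
           "graph_edge_list"]


@dataclass
class ConnectivityMatrix:
    """N x N symmetric Pearson matrix with named ROIs."""

    values: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if len(self.roi_names) != n:
            raise ValueError("roi_names length must match matrix size")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("connectivity matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1.0 + 1e-10):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightedGraph:
    """Dense non-negative weighted graph on the ROI node set.

    ``weights[i, j]`` is the undirected edge weight (zero = no edge, zero
    diagonal).  ``negative_policy`` records how signed correlations were
    mapped to weights.
    """

    weights: np.ndarray
    node_names: list[str]
    negative_policy: str

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if len(self.node_names) != n:
            raise ValueError("node_names length must match weight matrix")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return self.weights > 0

    def neighbors(self, v: int) -> np.ndarray:
        return np.flatnonzero(self.weights[v] > 0)


def pearson_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of the ROI columns of one subject."""
    x = ts.values
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"ROI column {bad} has zero variance; "
                         "Pearson correlation is undefined")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    names = [f"ROI{i + 1:03d}" for i in range(x.shape[1])]
    return ConnectivityMatrix(corr, names)


def to_weighted_graph(cm: ConnectivityMatrix, negative_policy: str = "absolute",
                      keep_fraction: float | None = None) -> WeightedGraph:
    """Map signed correlations to non-negative walk weights.

    ``keep_fraction``, if given, applies a proportional threshold: only the
    strongest fraction of off-diagonal ``|PC|`` entries keep an edge (a
    sensitivity-analysis option; the unthresholded graph is canonical).
    """
    if negative_policy not in ("absolute", "clip"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    c = cm.values.copy()
    np.fill_diagonal(c, 0.0)
    if keep_fraction is not None:
        if not 0 < keep_fraction <= 1:
            raise ValueError("keep_fraction must lie in (0, 1]")
        offdiag = np.abs(c[np.triu_indices_from(c, k=1)])
        if keep_fraction < 1:
            cutoff = np.quantile(offdiag, 1.0 - keep_fraction)
            c[np.abs(c) < cutoff] = 0.0
    w = np.abs(c) if negative_policy == "absolute" else np.clip(c, 0.0, None)
    graph = WeightedGraph(w, list(cm.roi_names), negative_policy)
    isolated = np.flatnonzero(w.sum(axis=1) == 0)
    if isolated.size:
        warnings.warn(
            f"{isolated.size} isolated node(s) under policy {negative_policy!r} "
            f"(first: {cm.roi_names[isolated[0]]}); walks from them terminate "
            "immediately", stacklevel=2)
    return graph


def save_connectivity(cm: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.values, index=cm.roi_names, columns=cm.roi_names).to_csv(
        path, sep="\t", float_format="%.10g")


def load_connectivity(path: str | Path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(frame.to_numpy(dtype=float), list(frame.columns))


def graph_edge_list(g: WeightedGraph) -> pd.DataFrame:
    """Weighted undirected edge list (node_i, node_j, weight), i < j."""
    i, j = np.triu_indices(g.n_nodes, k=1)
    keep = g.weights[i, j] > 0
    return pd.DataFrame({
        "node_i": [g.node_names[a] for a in i[keep]],
        "node_j": [g.node_names[b] for b in j[keep]],
        "weight": g.weights[i[keep], j[keep]],
    })
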