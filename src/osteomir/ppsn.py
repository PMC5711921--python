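"""Participant-participant similarity network and density-peak clustering.

Participants are points in the normalized model-input space; an undirected
edge joins two participants whose Euclidean distance falls below a threshold
(default 0.198).  Clustering follows the density-peak idea: each point gets a
local density rho (neighbors within a cutoff d_c) and a separation delta
(distance to the nearest point of higher density; the densest point takes the
maximum distance instead), cluster centers are the points with outstanding
gamma = rho * delta, and every remaining point joins the cluster of its
nearest denser neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, squareform

from .cohort import CohortTable, NormalizationParams

DEFAULT_EDGE_THRESHOLD = 0.198


def build_ppsn(
    cohort: CohortTable,
    normalization: NormalizationParams,
    features,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> nx.Graph:
    """Similarity graph over the cohort: edges where distance < threshold."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    X = normalization.transform(cohort, features)
    ids = cohort.ids
    status = [s.value for s in cohort.status()]
    g = nx.Graph()
    for pid, st in zip(ids, status):
        g.add_node(str(pid), status=st)
    D = cdist(X, X)
    n = len(X)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] < threshold:
                g.add_edge(str(ids[i]), str(ids[j]), weight=float(D[i, j]))
    return g


@dataclass
class DensityPeakResult:
    ids: np.ndarray
    density: np.ndarray        # rho_i: neighbors within d_c
    delta: np.ndarray          # distance to nearest denser point
    gamma: np.ndarray          # rho * delta
    centers: np.ndarray        # indices of cluster centers
    assignment: np.ndarray     # cluster index per node

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=len(self.centers))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "density": self.density, "delta": self.delta,
            "gamma": self.gamma, "cluster": self.assignment,
        })


def _auto_n_centers(gamma: np.ndarray) -> int:
    """Largest absolute gap in the sorted gamma sequence (candidates capped at 10)."""
    n = len(gamma)
    if n == 1:
        return 1
    g = np.sort(gamma)[::-1]
    limit = min(10, n - 1)
    gaps = g[:limit] - g[1:limit + 1]
    return int(np.argmax(gaps)) + 1


def density_peak_cluster(
    distances: np.ndarray,
    d_c: float = DEFAULT_EDGE_THRESHOLD,
    k_centers: int | None = None,
    ids=None,
) -> DensityPeakResult:
    """Density-peak clustering on a full symmetric distance matrix.

    Density ties break by index order: among equal densities the lower index
    counts as denser, which keeps the assignment deterministic for duplicate
    points.  ``k_centers`` overrides the automatic largest-gap choice.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim == 1:
        D = squareform(D)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("need a full symmetric distance matrix")
    if d_c <= 0:
        raise ValueError("d_c must be > 0")
    n = D.shape[0]
    ids = np.asarray(ids if ids is not None else np.arange(n), dtype=object)

    off = ~np.eye(n, dtype=bool)
    density = np.array([(D[i][off[i]] < d_c).sum() for i in range(n)], dtype=float)
    # rank: higher density first, lower index wins ties
    order = np.lexsort((np.arange(n), -density))
    delta = np.zeros(n)
    nearest_denser = np.full(n, -1)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = D[i].max() if n > 1 else 0.0
            continue
        denser = order[:pos]
        j = denser[np.argmin(D[i, denser])]
        delta[i] = D[i, j]
        nearest_denser[i] = j
    gamma = density * delta

    k = k_centers if k_centers is not None else _auto_n_centers(gamma)
    k = max(1, min(k, n))
    # centers: top-k by gamma, ties toward lower index
    center_order = np.lexsort((np.arange(n), -gamma))
    centers = np.sort(center_order[:k])

    assignment = np.full(n, -1)
    for c_label, c in enumerate(centers):
        assignment[c] = c_label
    for i in order:  # descending density: parents are assigned first
        if assignment[i] == -1:
            assignment[i] = assignment[nearest_denser[i]]
    return DensityPeakResult(ids, density, delta, gamma, centers, assignment)


# ---------------------------------------------------------------------------
# Graph export / import
# ---------------------------------------------------------------------------

def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write the similarity graph as GraphML or SIF (status as node attribute)."""
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            written = set()
            for u, v in graph.edges():
                fh.write(f"{u}\tsimilar\t{v}\n")
                written.update((u, v))
            for node in graph.nodes():
                if node not in written:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def import_graph(path, format: str = "graphml") -> nx.Graph:
    fmt = format.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[2])
        return g
    raise ValueError(f"unknown format {format!r}")
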