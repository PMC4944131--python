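"""Control-free mutual-information network inference.

Pairwise MI between gene profiles across samples is estimated either by
the discrete plug-in estimator on a contingency table or by the Kraskov
k-nearest-neighbour estimator on continuous values.  Indirect edges are
pruned with the data-processing inequality (DPI): in any triple of
genes, the weakest edge is removed if it is weaker than both others by
more than a tolerance, mirroring ARACNe.  The surviving matrix is
thresholded into an undirected network and connected components of a
minimum size are reported as gene clusters.

All MI values are in nats.
"""

from __future__ import annotations

import logging
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

log = logging.getLogger(__name__)


def entropy(probs: Sequence[float]) -> float:
    """Shannon entropy -sum p ln p in nats; 0 ln 0 = 0."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def mutual_information_plugin(joint: np.ndarray) -> float:
    """Plug-in MI from a 2D contingency table: S(X) + S(Y) - S(X,Y)."""
    table = np.asarray(joint, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("joint must be a non-negative 2D table")
    total = table.sum()
    if total <= 0:
        raise ValueError("contingency table is empty")
    p = table / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    return entropy(px) + entropy(py) - entropy(p.ravel())


def mutual_information_knn(
    x: Sequence[float],
    y: Sequence[float],
    k: int = 3,
    seed: int = 0,
) -> float:
    """Kraskov (algorithm 1) kNN MI estimate in nats, floored at 0.

    Ties are broken by adding infinitesimal jitter (1e-10 of the value
    range) from a generator seeded with ``seed``, so repeated calls are
    deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} samples, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant vector passed to kNN MI estimator; returning 0")
        return 0.0
    rng = np.random.default_rng(seed)
    xj = x + rng.normal(0.0, 1e-10 * np.ptp(x), n)
    yj = y + rng.normal(0.0, 1e-10 * np.ptp(y), n)
    pts = np.column_stack([xj, yj])
    tree = cKDTree(pts)
    # distance to the k-th neighbour in the max norm
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, k]
    tx = cKDTree(xj[:, None])
    ty = cKDTree(yj[:, None])
    shrunk = eps * (1.0 - 1e-12)  # count marginal neighbours strictly inside eps
    nx_counts = np.array([
        len(tx.query_ball_point([xj[i]], shrunk[i])) - 1 for i in range(n)
    ])
    ny_counts = np.array([
        len(ty.query_ball_point([yj[i]], shrunk[i])) - 1 for i in range(n)
    ])
    mi = (digamma(k) + digamma(n)
          - np.mean(digamma(nx_counts + 1) + digamma(ny_counts + 1)))
    return max(float(mi), 0.0)


def _discretize(values: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")


def mi_matrix(
    matrix: pd.DataFrame,
    estimator: str = "knn",
    k: int = 3,
    bins: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetric genes x genes MI matrix across samples (diagonal zero)."""
    n_samples = matrix.shape[1]
    if n_samples < 8:
        log.warning("MI estimation from only %d samples is unstable", n_samples)
    genes = matrix.index
    x = matrix.to_numpy(dtype=float)
    p = len(genes)
    out = np.zeros((p, p))
    if estimator == "knn":
        for i in range(p):
            for j in range(i + 1, p):
                out[i, j] = out[j, i] = mutual_information_knn(
                    x[i], x[j], k=k, seed=seed + i * p + j
                )
    elif estimator == "plugin":
        disc = np.vstack([_discretize(row, bins) for row in x])
        for i in range(p):
            for j in range(i + 1, p):
                table = np.zeros((bins, bins))
                np.add.at(table, (disc[i], disc[j]), 1)
                out[i, j] = out[j, i] = mutual_information_plugin(table)
    else:
        raise ValueError(f"unknown estimator {estimator!r}; expected 'knn' or 'plugin'")
    return pd.DataFrame(out, index=genes, columns=genes)


def dpi_prune(mi: pd.DataFrame, eps: float = 0.05) -> pd.DataFrame:
    """One-pass ARACNe data-processing-inequality pruning.

    For every triple (i, j, k), the edge (i, j) is removed when
    ``MI(i,j) < min(MI(i,k), MI(j,k)) - eps``.  All comparisons use the
    original matrix, so removals do not cascade within the pass.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    m = mi.to_numpy(dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    p = m.shape[0]
    keep = np.ones_like(m, dtype=bool)
    for i in range(p):
        # strongest indirect path i-k-j for all j at once
        through = np.minimum(m[i][:, None], m)  # [k, j]
        np.fill_diagonal(through, -np.inf)
        through[i, :] = -np.inf
        best = through.max(axis=0)  # over k, per j
        keep[i] = ~(m[i] < best - eps)
    keep &= keep.T
    pruned = np.where(keep, m, 0.0)
    np.fill_diagonal(pruned, 0.0)
    return pd.DataFrame(pruned, index=mi.index, columns=mi.columns)


def threshold_network(
    mi: pd.DataFrame, min_mi: float, strict: bool = False
) -> nx.Graph:
    """Keep edges with MI >= min_mi (or > with ``strict``); drop isolated nodes."""
    if min_mi < 0:
        raise ValueError("min_mi must be >= 0")
    m = mi.to_numpy(dtype=float)
    genes = list(mi.index)
    g = nx.Graph()
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = m[iu, ju]
    mask = vals > min_mi if strict else vals >= min_mi
    if min_mi == 0:
        mask &= vals > 0  # a zero entry is "no edge", not an edge of weight 0
    for i, j, v in zip(iu[mask], ju[mask], vals[mask]):
        g.add_edge(genes[i], genes[j], weight=float(v))
    return g


def extract_clusters(net: nx.Graph, min_size: int = 10) -> tuple[list[set], nx.Graph]:
    """Connected components with >= min_size nodes, largest first.

    Returns the component node sets and the subnetwork induced by their
    union.
    """
    comps = [set(c) for c in nx.connected_components(net)]
    big = sorted(
        (c for c in comps if len(c) >= min_size),
        key=lambda c: (-len(c), min(map(str, c))),
    )
    union: set = set().union(*big) if big else set()
    return big, net.subgraph(union).copy()


def write_edge_list(net: nx.Graph, path: str) -> None:
    with open(path, "w") as out:
        out.write("gene_a\tgene_b\tweight\n")
        for a, b, data in sorted(net.edges(data=True)):
            out.write(f"{a}\t{b}\t{data.get('weight', 1.0):.6g}\n")


def read_edge_list(path: str) -> nx.Graph:
    g = nx.Graph()
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: expected edge-list header")
        for line in handle:
            a, b, w = line.rstrip("\n").split("\t")
            g.add_edge(a, b, weight=float(w))
    return g
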