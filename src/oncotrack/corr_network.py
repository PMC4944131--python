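"""Pearson-correlation gene networks with hard +/-0.95 quantization.

Gene-gene correlations across samples are quantized to {-1, 0, +1}
(strictly above the threshold is +1, strictly below its negation is
-1), giving positive, negative and complete (union) networks.  The
module also compares two such networks — typically germline vs tumour
from the same patients — through their per-gene degree (link) vectors:
an overall degree correlation, the same correlation within consecutive
windows of genes along each chromosome (to localize rewired regions),
and a ranked per-gene degree-change table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from oncotrack.gene_model import CollapsedGene

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.95


def pearson_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations across samples.

    Genes with constant profiles have undefined correlations; these are
    set to 0 and a warning names how many were masked.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for gene-gene correlations")
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d constant gene(s): correlations masked to 0", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    return pd.DataFrame(r, index=matrix.index, columns=matrix.index)


def sample_correlations(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    drop: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-sample-pair correlation across genes, before/after dropping genes.

    Columns of the two matrices are matched positionally (pair i of
    ``matrix_a`` with pair i of ``matrix_b``); gene axes must be equal.
    ``drop`` lists gene symbols (e.g. the coverage outlier TTN) removed
    for the second correlation.
    """
    if not matrix_a.index.equals(matrix_b.index):
        raise ValueError("gene axes of the two matrices differ")
    if matrix_a.shape[1] != matrix_b.shape[1]:
        raise ValueError("matrices must have the same number of samples")
    symbols = matrix_a.index.to_series().str.split("|").str[0]
    keep = ~symbols.isin(set(drop)).to_numpy()
    rows = []
    for i, (ca, cb) in enumerate(zip(matrix_a.columns, matrix_b.columns)):
        a = matrix_a[ca].to_numpy(dtype=float)
        b = matrix_b[cb].to_numpy(dtype=float)
        r_all = _safe_corr(a, b)
        r_drop = _safe_corr(a[keep], b[keep]) if len(drop) else r_all
        rows.append({"pair": i, "sample_a": ca, "sample_b": cb,
                     "r": r_all, "r_dropped": r_drop})
    return pd.DataFrame(rows)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def quantize(pc: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Quantize correlations: r > threshold -> +1, r < -threshold -> -1, else 0."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    r = pc.to_numpy(dtype=float)
    q = np.zeros_like(r, dtype=np.int8)
    q[r > threshold] = 1
    q[r < -threshold] = -1
    np.fill_diagonal(q, 0)
    return pd.DataFrame(q, index=pc.index, columns=pc.columns)


@dataclass
class CorrelationNetworks:
    """Positive, negative, and complete (union) quantized networks."""

    positive: nx.Graph
    negative: nx.Graph
    complete: nx.Graph


def build_networks(q: pd.DataFrame) -> CorrelationNetworks:
    """Build the three signed networks from a quantized adjacency."""
    genes = list(q.index)
    m = q.to_numpy()
    pos, neg, comp = nx.Graph(), nx.Graph(), nx.Graph()
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        v = int(m[i, j])
        if v == 0:
            continue
        a, b = genes[i], genes[j]
        comp.add_edge(a, b, sign=v)
        (pos if v > 0 else neg).add_edge(a, b, sign=v)
    return CorrelationNetworks(positive=pos, negative=neg, complete=comp)


def top_linked_genes(net: nx.Graph, n: int = 15) -> pd.DataFrame:
    """Top-n genes by degree; ties broken by locus_id."""
    ranked = sorted(net.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    return pd.DataFrame(ranked[:n], columns=["locus_id", "degree"])


def degree_vector(net: nx.Graph, universe: Sequence[str]) -> np.ndarray:
    """Per-gene degrees over a fixed gene universe (absent gene -> 0)."""
    deg = dict(net.degree())
    return np.array([deg.get(g, 0) for g in universe], dtype=float)


def link_correlation(
    net_a: nx.Graph, net_b: nx.Graph, universe: Sequence[str] | None = None
) -> float:
    """Pearson r between the degree vectors of two networks (NaN if undefined)."""
    if universe is None:
        universe = sorted(set(net_a.nodes) | set(net_b.nodes), key=str)
    da = degree_vector(net_a, universe)
    db = degree_vector(net_b, universe)
    return _safe_corr(da, db)


def windowed_link_correlation(
    net_a: nx.Graph,
    net_b: nx.Graph,
    model: Sequence[CollapsedGene],
    window: int = 50,
    low: float = 0.3,
    high: float = 0.95,
) -> pd.DataFrame:
    """Degree correlation in consecutive windows of genes along chromosomes.

    Genes are ordered by (chrom, start); each chromosome is cut into
    non-overlapping windows of ``window`` genes (a trailing remainder is
    kept when it has at least window/2 genes, otherwise folded into the
    previous window).  Windows with |r| < ``low`` are flagged "deviant",
    r > ``high`` "conserved"; windows whose degree vector is constant in
    either network get r = NaN and no flag.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    ordered = sorted(model, key=lambda g: (g.chrom, g.start, g.locus_id))
    rows = []
    by_chrom: dict[str, list[CollapsedGene]] = {}
    for g in ordered:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        bounds = list(range(0, len(genes), window))
        spans = [(s, min(s + window, len(genes))) for s in bounds]
        if len(spans) > 1 and spans[-1][1] - spans[-1][0] < window / 2:
            last = spans.pop()
            spans[-1] = (spans[-1][0], last[1])
        for w_idx, (s, e) in enumerate(spans):
            ids = [g.locus_id for g in genes[s:e]]
            da = degree_vector(net_a, ids)
            db = degree_vector(net_b, ids)
            r = _safe_corr(da, db)
            if np.isnan(r):
                flag = ""
            elif abs(r) < low:
                flag = "deviant"
            elif r > high:
                flag = "conserved"
            else:
                flag = ""
            rows.append({
                "chrom": chrom, "window": w_idx,
                "start_gene": ids[0], "end_gene": ids[-1],
                "n_genes": len(ids), "r": r, "flag": flag,
            })
    return pd.DataFrame(rows)


def degree_change(
    net_a: nx.Graph, net_b: nx.Graph, universe: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene degree difference (net_b - net_a), largest losses first."""
    if universe is None:
        universe = sorted(set(net_a.nodes) | set(net_b.nodes), key=str)
    da = degree_vector(net_a, universe)
    db = degree_vector(net_b, universe)
    out = pd.DataFrame({
        "locus_id": list(universe),
        "degree_a": da.astype(int),
        "degree_b": db.astype(int),
        "delta": (db - da).astype(int),
    })
    return out.sort_values(["delta", "locus_id"]).reset_index(drop=True)
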