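"""Gene-set over-representation analysis with GMT collections.

Each pathway's overlap with a query gene list is scored by the
upper-tail hypergeometric probability P(X >= k) of drawing k or more
pathway members in a query of size n from a universe of N genes, with
Benjamini-Hochberg adjustment across pathways.  Significant pathways
are also assembled into a pathway-gene bipartite network and its
gene-gene / pathway-pathway projections, with the most central node per
projection reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from oncotrack.diffexp import bh_adjust

log = logging.getLogger(__name__)

DEFAULT_UNIVERSE = 19358  # collapsed-model gene count for the human exome


@dataclass
class PathwaySet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")


class GmtParseError(ValueError):
    pass


def load_gmt(path: str | Path) -> list[PathwaySet]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: list[PathwaySet] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path} line {lineno}: expected >= 3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in seen:
                raise GmtParseError(f"{path} line {lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(PathwaySet(name=name, description=desc, genes=genes))
    if not sets:
        raise GmtParseError(f"{path}: no pathway lines found")
    return sets


@dataclass
class EnrichmentResult:
    pathway: str
    k_overlap: int
    set_size: int
    query_size: int
    universe_size: int
    pvalue: float
    padj: float = float("nan")
    overlap_genes: frozenset[str] = field(default_factory=frozenset)


def hypergeom_enrich(
    query: Sequence[str],
    sets: Sequence[PathwaySet],
    universe_size: int = DEFAULT_UNIVERSE,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment with BH adjustment across sets."""
    genes = set(query)
    n = len(genes)
    results = []
    for ps in sets:
        big_k = len(ps.genes)
        if universe_size < max(big_k, n):
            raise ValueError(
                f"universe ({universe_size}) smaller than set ({big_k}) or query ({n})"
            )
        overlap = genes & ps.genes
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, universe_size, big_k, n))
        results.append(EnrichmentResult(
            pathway=ps.name, k_overlap=k, set_size=big_k, query_size=n,
            universe_size=universe_size, pvalue=min(p, 1.0),
            overlap_genes=frozenset(overlap),
        ))
    padj = bh_adjust([r.pvalue for r in results])
    for r, adj in zip(results, padj):
        r.padj = float(adj)
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [{
        "pathway": r.pathway, "k": r.k_overlap, "K": r.set_size,
        "n": r.query_size, "N": r.universe_size,
        "pvalue": r.pvalue, "padj": r.padj,
        "genes": ",".join(sorted(r.overlap_genes)),
    } for r in results]
    return pd.DataFrame(rows).sort_values(["pvalue", "pathway"]).reset_index(drop=True)


@dataclass
class ProjectionNetworks:
    bipartite: nx.Graph
    gene_gene: nx.Graph
    pathway_pathway: nx.Graph
    central_gene: str | None
    central_pathway: str | None


def build_projection_networks(
    results: Sequence[EnrichmentResult],
    centrality: str = "degree",
) -> ProjectionNetworks:
    """Bipartite pathway-gene network of significant results plus projections.

    Genes are linked when they share a significant pathway; pathways are
    linked when they share an overlapping query gene.  The most central
    node of each projection (degree centrality by default, betweenness
    optionally) is reported with lexicographic tie-breaking.
    """
    if not results:
        raise ValueError("no enrichment results to project")
    bip = nx.Graph()
    for r in results:
        bip.add_node(r.pathway, kind="pathway")
        for g in sorted(r.overlap_genes):
            bip.add_node(g, kind="gene")
            bip.add_edge(r.pathway, g)
    genes = [n for n, d in bip.nodes(data=True) if d["kind"] == "gene"]
    pathways = [n for n, d in bip.nodes(data=True) if d["kind"] == "pathway"]
    gg = nx.Graph()
    gg.add_nodes_from(genes)
    pp = nx.Graph()
    pp.add_nodes_from(pathways)
    for r in results:
        members = sorted(r.overlap_genes)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                gg.add_edge(a, b)
    for i, ra in enumerate(results):
        for rb in results[i + 1:]:
            if ra.overlap_genes & rb.overlap_genes:
                pp.add_edge(ra.pathway, rb.pathway)
    return ProjectionNetworks(
        bipartite=bip,
        gene_gene=gg,
        pathway_pathway=pp,
        central_gene=_most_central(gg, centrality),
        central_pathway=_most_central(pp, centrality),
    )


def _most_central(net: nx.Graph, centrality: str) -> str | None:
    if net.number_of_nodes() == 0:
        return None
    if centrality == "degree":
        scores = nx.degree_centrality(net)
    elif centrality == "betweenness":
        scores = nx.betweenness_centrality(net)
    else:
        raise ValueError("centrality must be 'degree' or 'betweenness'")
    return min(scores, key=lambda n: (-scores[n], str(n)))
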