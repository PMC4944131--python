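"""Pipeline orchestration with reproducible run manifests.

Wires the stages — simulate (optional) -> spkmg -> diff -> minet ->
netstats -> enrich — in order, passing results between stages through
files named in the manifest.  The manifest records parameters, input
checksums, and elapsed time per stage so a run can be audited and
reproduced from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from oncotrack import diffexp, enrichment, gene_model, graph_metrics, mi_network
from oncotrack import spkmg as spkmg_mod
from oncotrack import synthetic_data as synth

log = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "spkmg", "diff", "minet", "netstats", "enrich"]


@dataclass
class RunConfig:
    """Validated pipeline configuration; serializes losslessly to JSON."""

    out_dir: str
    stages: list[str]
    seed: int | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = [s for s in STAGE_ORDER if s in self.stages]
        random_stages = {"simulate", "minet"} & set(self.stages)
        if random_stages and self.seed is None:
            raise ValueError(
                f"stages {sorted(random_stages)} need randomness: config must set a seed"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls(**json.load(handle))

    def to_json(self) -> str:
        return json.dumps({
            "out_dir": self.out_dir, "stages": self.stages,
            "seed": self.seed, "params": self.params,
        }, indent=2)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages in order; return the manifest dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": json.loads(cfg.to_json()),
        "stages": [],
    }
    state: dict[str, Any] = {"params": cfg.params, "seed": cfg.seed, "out": out_dir}
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            outputs = _STAGES[stage](state)
        except Exception:
            log.error("stage %r failed", stage)
            _write_manifest(manifest, out_dir, partial=True)
            raise
        entry = {
            "stage": stage,
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "outputs": {name: _checksum(Path(p)) for name, p in outputs.items()},
            "paths": {name: str(p) for name, p in outputs.items()},
        }
        manifest["stages"].append(entry)
        log.info("stage %s done in %.2fs", stage, entry["elapsed_s"])
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path, partial: bool = False) -> None:
    name = "manifest.json.partial" if partial else "manifest.json"
    with open(out_dir / name, "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)


def _stage_simulate(state: dict) -> dict:
    p = state["params"]
    out: Path = state["out"]
    cfg = synth.SimConfig(
        seed=state["seed"],
        n_genes=p.get("n_genes", 40),
        samples_per_group=p.get("samples_per_group", 5),
        base_coverage=p.get("base_coverage", 50.0),
        duplicate_fraction=p.get("duplicate_fraction", 0.1),
        low_quality_fraction=p.get("low_quality_fraction", 0.05),
    )
    model = synth.make_toy_model(cfg.n_genes, seed=state["seed"],
                                 refflat_path=out / "model.refflat")
    gene_model.write_gene_model(model, out / "model.exons.tsv", out / "model.genes.tsv")
    state["model"] = model
    loci = [g.locus_id for g in model]
    cnv = synth.CnvSpec(
        multipliers={loci[i]: m for i, m in
                     zip(range(0, len(loci), max(len(loci) // 5, 1)), [0.0, 0.5, 1.5, 2.0])},
    )
    sam_paths = []
    for group, n in (("case", cfg.samples_per_group), ("control", cfg.samples_per_group)):
        for i in range(n):
            sid = f"{group}{i + 1}"
            path = out / f"{sid}.sam"
            spec = cnv if group == "case" else synth.CnvSpec()
            synth.simulate_reads(model, spec, cfg, sid, path)
            sam_paths.append(path)
    state["sam_paths"] = sam_paths
    return {"model": out / "model.exons.tsv",
            **{p.stem: p for p in sam_paths}}


def _stage_spkmg(state: dict) -> dict:
    out: Path = state["out"]
    model = state.get("model") or gene_model.read_gene_model(
        state["params"]["model_path"])
    state["model"] = model
    sam_paths = state.get("sam_paths") or [
        Path(p) for p in state["params"]["sam_paths"]]
    samples = [spkmg_mod.count_exonic_reads(p, model) for p in sam_paths]
    matrix = spkmg_mod.build_matrix(samples, model)
    spkmg_mod.write_matrix(matrix, out / "spkmg.tsv")
    spkmg_mod.write_qc_table(samples, out / "spkmg.qc.tsv")
    state["matrix"] = matrix
    return {"matrix": out / "spkmg.tsv", "qc": out / "spkmg.qc.tsv"}


def _stage_diff(state: dict) -> dict:
    out: Path = state["out"]
    matrix: pd.DataFrame = state["matrix"]
    groups = [c.rstrip("0123456789") for c in matrix.columns]
    design = diffexp.GroupDesign(list(matrix.columns), groups)
    table = diffexp.differential_analysis(
        matrix, design, scale=state["params"].get("scale", 1.0))
    table.to_csv(out / "diff.tsv", sep="\t")
    state["diff"] = table
    return {"diff": out / "diff.tsv"}


def _stage_minet(state: dict) -> dict:
    out: Path = state["out"]
    p = state["params"]
    matrix: pd.DataFrame = state["matrix"]
    mi = mi_network.mi_matrix(matrix, estimator=p.get("estimator", "knn"),
                              k=p.get("k", 3), seed=state["seed"])
    pruned = mi_network.dpi_prune(mi, eps=p.get("eps", 0.05))
    net = mi_network.threshold_network(pruned, p.get("min_mi", 0.5))
    mi_network.write_edge_list(net, str(out / "mi.edges.tsv"))
    clusters, _ = mi_network.extract_clusters(net, p.get("min_cluster", 10))
    with open(out / "mi.clusters.tsv", "w") as handle:
        handle.write("cluster_id\tlocus_id\n")
        for idx, cluster in enumerate(clusters):
            for gene in sorted(cluster):
                handle.write(f"{idx}\t{gene}\n")
    state["mi_net"] = net
    return {"edges": out / "mi.edges.tsv", "clusters": out / "mi.clusters.tsv"}


def _stage_netstats(state: dict) -> dict:
    out: Path = state["out"]
    net = state["mi_net"]
    if net.number_of_nodes() >= 2:
        summary = graph_metrics.summarize_network(net).to_dict()
    else:
        summary = {"n_nodes": net.number_of_nodes(),
                   "n_edges": net.number_of_edges(), "note": "too small"}
    with open(out / "netstats.json", "w") as handle:
        json.dump(summary, handle, indent=2)
    return {"summary": out / "netstats.json"}


def _stage_enrich(state: dict) -> dict:
    out: Path = state["out"]
    p = state["params"]
    table: pd.DataFrame = state["diff"]
    alpha = p.get("alpha", 0.05)
    query = [lid.split("|")[0] for lid in table.index[table["padj"] < alpha]]
    sets = enrichment.load_gmt(p["gmt_path"]) if "gmt_path" in p else \
        _default_toy_sets(state)
    results = enrichment.hypergeom_enrich(
        query, sets, universe_size=p.get("universe", max(len(table), 1)))
    enrichment.results_table(results).to_csv(out / "enrich.tsv", sep="\t", index=False)
    return {"enrich": out / "enrich.tsv"}


def _default_toy_sets(state: dict) -> list:
    # partition the simulated genes into five toy "pathways"
    model = state["model"]
    symbols = [g.symbol for g in model]
    chunk = max(len(symbols) // 5, 1)
    return [
        enrichment.PathwaySet(
            name=f"TOY_PATHWAY_{i + 1}", description="simulated",
            genes=frozenset(symbols[i * chunk:(i + 1) * chunk] or symbols[-chunk:]),
        )
        for i in range(5)
    ]


_STAGES = {
    "simulate": _stage_simulate,
    "spkmg": _stage_spkmg,
    "diff": _stage_diff,
    "minet": _stage_minet,
    "netstats": _stage_netstats,
    "enrich": _stage_enrich,
}
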