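"""Seeded synthetic data for every pipeline stage.

Real inputs to the method are exome alignments over a reference gene
model.  This module emulates them at desk scale: a toy collapsed gene
model over a few chromosomes, SAM alignments whose per-gene read depth
follows Poisson coverage scaled by a per-gene copy-number multiplier
(0 = homozygous deletion, 0.5 = hemizygous loss, 1 = neutral, >= 1.5 =
amplification) with PCR-duplicate-flagged and low-mapping-quality reads
mixed in, negative-binomial count matrices with planted fold changes
for the case/control stage, modular correlated expression for the
network stages, and discrete power-law degree samples.

Every generator takes an explicit seed and is a pure function of its
arguments; ground-truth tables are returned alongside the data so test
oracles never recompute the simulation's internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from oncotrack.gene_model import CollapsedGene, ExonInterval

READ_LENGTH = 100
LOW_MAPQ = 10
GOOD_MAPQ = 60


@dataclass
class SimConfig:
    """Knobs for the read simulator; defaults emulate a small exome cohort."""

    seed: int
    n_genes: int = 50
    samples_per_group: int = 10
    base_coverage: float = 50.0     # reads per median-length gene
    duplicate_fraction: float = 0.1
    low_quality_fraction: float = 0.05
    dispersion: float = 0.1         # NB dispersion for count matrices
    fold_change: float = 2.0
    affected_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in ("duplicate_fraction", "low_quality_fraction", "affected_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class CnvSpec:
    """Per-locus copy multipliers for chosen samples; default multiplier 1."""

    multipliers: Mapping[str, float] = field(default_factory=dict)  # locus_id -> m
    affected_samples: frozenset[str] = frozenset()

    def multiplier(self, locus_id: str, sample_id: str) -> float:
        if self.affected_samples and sample_id not in self.affected_samples:
            return 1.0
        m = self.multipliers.get(locus_id, 1.0)
        if m < 0:
            raise ValueError(f"copy multiplier must be >= 0, got {m}")
        return m


def make_toy_model(
    n_genes: int,
    exons_per_gene: int = 3,
    n_chroms: int = 3,
    seed: int = 0,
    refflat_path: str | Path | None = None,
) -> list[CollapsedGene]:
    """Deterministic non-overlapping gene model with varied exonic lengths.

    Exonic lengths are drawn log-uniformly in roughly 0.5-10 kb.  When
    ``refflat_path`` is given, an equivalent single-isoform refFlat file
    is written so the model round-trips through the loader.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    genes: list[CollapsedGene] = []
    cursors = {f"chr{i + 1}": 10_000 for i in range(n_chroms)}
    for idx in range(n_genes):
        chrom = f"chr{(idx % n_chroms) + 1}"
        pos = cursors[chrom]
        exons = []
        target = float(rng.uniform(np.log(500), np.log(10_000)))
        exon_len = max(int(np.exp(target)) // exons_per_gene, READ_LENGTH)
        for _ in range(exons_per_gene):
            exons.append(ExonInterval(chrom, pos, pos + exon_len))
            pos += exon_len + int(rng.integers(200, 2_000))  # intron
        cursors[chrom] = pos + 50_000  # intergenic gap
        symbol = f"GENE{idx:04d}"
        genes.append(CollapsedGene(
            symbol=symbol,
            locus_id=f"{symbol}|{chrom}|0",
            chrom=chrom,
            strand="+",
            exons=exons,
        ))
    genes.sort(key=lambda g: (g.chrom, g.start, g.locus_id))
    if refflat_path is not None:
        with open(refflat_path, "w") as out:
            for g in genes:
                starts = ",".join(str(e.start) for e in g.exons) + ","
                ends = ",".join(str(e.end) for e in g.exons) + ","
                out.write("\t".join([
                    g.symbol, f"{g.symbol}_tx", g.chrom, g.strand,
                    str(g.start), str(g.end), str(g.start), str(g.end),
                    str(len(g.exons)), starts, ends,
                ]) + "\n")
    return genes


def _sam_header(model: Sequence[CollapsedGene]) -> dict:
    chrom_ends: dict[str, int] = {}
    for g in model:
        chrom_ends[g.chrom] = max(chrom_ends.get(g.chrom, 0), g.end + 10_000)
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": end} for c, end in sorted(chrom_ends.items())],
    }


def make_capture_efficiency(
    model: Sequence[CollapsedGene], seed: int, sigma: float = 1.0
) -> dict[str, float]:
    """Lognormal per-gene capture-efficiency profile.

    Real exome capture is non-uniform gene to gene but the profile is
    shared across samples prepared with the same kit; passing the same
    profile to several samples reproduces the strong between-sample
    SPKMG correlation seen in practice.
    """
    rng = np.random.default_rng(seed)
    return {g.locus_id: float(rng.lognormal(0.0, sigma)) for g in model}


def simulate_reads(
    model: Sequence[CollapsedGene],
    cnv: CnvSpec,
    cfg: SimConfig,
    sample_id: str,
    sam_path: str | Path,
    efficiency: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Write one sample's SAM file; return the per-gene ground truth.

    Per gene, the clean read count is Poisson with mean
    ``base_coverage * m * efficiency * exonic_length / median_length``;
    reads of length 100 are placed uniformly within exons, so each read
    overlaps exactly one gene.  ``duplicate_fraction`` of clean reads
    gain a flagged PCR-duplicate copy, and ``low_quality_fraction``
    extra reads carry mapping quality below 20.  The truth table
    records the expected post-filter count R per gene and the
    post-filter total G (columns: locus_id, multiplier, R; attrs: G).
    """
    rng = np.random.default_rng(cfg.seed + _stable_hash(sample_id))
    lengths = np.array([g.exonic_length for g in model], dtype=float)
    median_len = float(np.median(lengths))
    header = _sam_header(model)
    truth_rows = []
    total_clean = 0
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
        serial = 0
        for g in model:
            m = cnv.multiplier(g.locus_id, sample_id)
            eff = efficiency.get(g.locus_id, 1.0) if efficiency else 1.0
            mean = cfg.base_coverage * m * eff * g.exonic_length / median_len
            n_clean = int(rng.poisson(mean)) if mean > 0 else 0
            n_low = int(rng.poisson(mean * cfg.low_quality_fraction)) if mean > 0 else 0
            total_clean += n_clean
            for kind, count in (("clean", n_clean), ("lowq", n_low)):
                for _ in range(count):
                    serial += 1
                    read = _place_read(g, rng, ref_ids, serial)
                    if kind == "lowq":
                        read.mapping_quality = LOW_MAPQ
                    out.write(read)
                    if kind == "clean" and rng.random() < cfg.duplicate_fraction:
                        dup = _clone_read(read, serial)
                        dup.is_duplicate = True
                        out.write(dup)
            truth_rows.append({"locus_id": g.locus_id, "multiplier": m, "R": n_clean})
    truth = pd.DataFrame(truth_rows)
    truth.attrs["G"] = total_clean
    truth.attrs["sample_id"] = sample_id
    return truth


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h


def _place_read(
    gene: CollapsedGene, rng: np.random.Generator, ref_ids: dict, serial: int
) -> pysam.AlignedSegment:
    weights = np.array([e.length for e in gene.exons], dtype=float)
    exon = gene.exons[int(rng.choice(len(gene.exons), p=weights / weights.sum()))]
    length = min(READ_LENGTH, exon.length)
    start = int(rng.integers(exon.start, exon.end - length + 1))
    read = pysam.AlignedSegment()
    read.query_name = f"read{serial:08d}"
    read.query_sequence = "A" * length
    read.query_qualities = pysam.qualitystring_to_array("I" * length)
    read.reference_id = ref_ids[gene.chrom]
    read.reference_start = start
    read.cigarstring = f"{length}M"
    read.mapping_quality = GOOD_MAPQ
    read.flag = 0
    return read


def _clone_read(read: pysam.AlignedSegment, serial: int) -> pysam.AlignedSegment:
    dup = pysam.AlignedSegment()
    dup.query_name = f"dup{serial:08d}"
    dup.query_sequence = read.query_sequence
    dup.query_qualities = read.query_qualities
    dup.reference_id = read.reference_id
    dup.reference_start = read.reference_start
    dup.cigarstring = read.cigarstring
    dup.mapping_quality = read.mapping_quality
    dup.flag = 0
    return dup


def simulate_counts_nb(
    cfg: SimConfig,
    n_genes: int | None = None,
    base_mean: float = 100.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB count matrix for a two-group design with planted fold changes.

    Returns (counts, truth) where truth is a boolean Series marking the
    genes whose group-B mean was multiplied by ``cfg.fold_change``.
    Dispersion ``cfg.dispersion`` = 0 gives the Poisson limit.
    """
    if cfg.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    p = n_genes or cfg.n_genes
    n_per = cfg.samples_per_group
    mu = rng.uniform(0.5, 2.0, p) * base_mean
    affected = np.zeros(p, dtype=bool)
    n_aff = int(round(p * cfg.affected_fraction))
    affected[rng.choice(p, n_aff, replace=False)] = True
    genes = [f"GENE{i:04d}|chr1|0" for i in range(p)]
    cols = {}
    for group, label in ((0, "A"), (1, "B")):
        for s in range(n_per):
            mean = mu * np.where(affected & (group == 1), cfg.fold_change, 1.0)
            if cfg.dispersion < 1e-12:
                draw = rng.poisson(mean)
            else:
                shape = 1.0 / cfg.dispersion
                lam = rng.gamma(shape, mean / shape)
                draw = rng.poisson(lam)
            cols[f"{label}{s + 1}"] = draw
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="locus_id"))
    return counts, pd.Series(affected, index=counts.index, name="affected")


def simulate_modular_expression(
    seed: int,
    module_sizes: Sequence[int],
    n_samples: int = 20,
    rho_within: float = 0.9,
    n_background: int = 0,
    flip_fraction: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Latent-factor expression with planted correlated modules.

    Genes in a module share a latent factor so pairwise within-module
    correlation is about ``rho_within``; between-module correlation is
    about 0.  ``flip_fraction`` of each module's genes are sign-flipped
    to create negative correlations across the flip boundary.  Returns
    (matrix, module labels; background genes labelled -1).
    """
    if rho_within < 0 or rho_within >= 1:
        raise ValueError("rho_within must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    load = np.sqrt(rho_within)
    noise_sd = np.sqrt(1.0 - rho_within)
    gene_idx = 0
    for mod, size in enumerate(module_sizes):
        factor = rng.normal(0.0, 1.0, n_samples)
        n_flip = int(round(size * flip_fraction))
        for within_idx in range(size):
            sign = -1.0 if within_idx < n_flip else 1.0
            profile = sign * load * factor + noise_sd * rng.normal(0.0, 1.0, n_samples)
            rows.append(profile)
            labels.append(mod)
            gene_idx += 1
    for _ in range(n_background):
        rows.append(rng.normal(0.0, 1.0, n_samples))
        labels.append(-1)
        gene_idx += 1
    genes = [f"GENE{i:04d}|chr1|0" for i in range(gene_idx)]
    matrix = pd.DataFrame(np.vstack(rows), index=pd.Index(genes, name="locus_id"),
                          columns=[f"S{j + 1}" for j in range(n_samples)])
    return matrix, pd.Series(labels, index=matrix.index, name="module")


def simulate_power_law_degrees(
    alpha: float, n: int, kmin: int = 1, seed: int = 0, kmax: int = 1_000_000
) -> np.ndarray:
    """i.i.d. draws from the discrete power law p(k) ~ k^-alpha, k >= kmin.

    Inverse-CDF sampling on the zeta-normalized mass, truncated at
    ``kmax`` (the omitted tail mass is far below 1/n for alpha > 1.5).
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    rng = np.random.default_rng(seed)
    ks = np.arange(kmin, kmax + 1, dtype=float)
    mass = ks ** -alpha
    cdf = np.cumsum(mass)
    cdf /= cdf[-1]
    u = rng.random(n)
    return (np.searchsorted(cdf, u, side="left") + kmin).astype(int)
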