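"""SPKMG computation from exome alignments.

SPKMG (Sequence Per Kilobase of exon, per Megabase of the mappable
Genome) normalizes the exonic read count R of a gene by the gene's
exonic length E and the sample's total aligned read count G:

    SPKMG = 1e9 * R / (E * G)

i.e. reads per kilobase of exon per million aligned reads — the same
scaling as RPKM, applied to DNA read depth.  Because exome capture
samples the genome roughly uniformly within targets, SPKMG tracks the
local copy number of a gene: 0 for a homozygous deletion, depressed for
a hemizygous loss, elevated for an amplification.

Reads are cleaned before counting: unmapped, secondary and
PCR-duplicate alignments are dropped, as are reads with mapping quality
below a Phred threshold (default 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from oncotrack.gene_model import CollapsedGene

log = logging.getLogger(__name__)

SPKMG_SCALE = 1e9  # kilobase (1e3) x million reads (1e6)
DEFAULT_MIN_QUALITY = 20


@dataclass
class FilterStats:
    """Per-sample read-cleaning bookkeeping."""

    total: int = 0
    unmapped: int = 0
    secondary: int = 0
    duplicate: int = 0
    low_quality: int = 0
    kept: int = 0


@dataclass
class SampleCounts:
    """Exonic read counts R per locus and total aligned reads G for one sample."""

    sample_id: str
    counts: dict[str, int]
    total_aligned: int
    filter_stats: FilterStats = field(default_factory=FilterStats)


def _read_quality(read: pysam.AlignedSegment, metric: str) -> float:
    if metric == "mapping":
        return read.mapping_quality
    if metric == "base":
        quals = read.query_qualities
        return float(np.mean(quals)) if quals is not None else 0.0
    raise ValueError(f"unknown quality metric {metric!r}; expected 'mapping' or 'base'")


def filter_reads(
    reads: Iterable[pysam.AlignedSegment],
    min_quality: int = DEFAULT_MIN_QUALITY,
    drop_duplicates: bool = True,
    stats: FilterStats | None = None,
    quality_metric: str = "mapping",
) -> Iterator[pysam.AlignedSegment]:
    """Yield reads surviving the cleaning filters.

    Unmapped and secondary/supplementary alignments are always removed;
    duplicate-flagged reads are removed when ``drop_duplicates``; reads
    with Phred quality strictly below ``min_quality`` are removed, where
    the quality is the mapping quality (default) or the mean base
    quality (``quality_metric="base"``).
    """
    own_stats = stats if stats is not None else FilterStats()
    for read in reads:
        own_stats.total += 1
        if read.is_unmapped:
            own_stats.unmapped += 1
            continue
        if read.is_secondary or read.is_supplementary:
            own_stats.secondary += 1
            continue
        if drop_duplicates and read.is_duplicate:
            own_stats.duplicate += 1
            continue
        if _read_quality(read, quality_metric) < min_quality:
            own_stats.low_quality += 1
            continue
        own_stats.kept += 1
        yield read
    log.info(
        "filter_reads: %d total, %d unmapped, %d secondary, %d duplicate, "
        "%d low-quality, %d kept",
        own_stats.total, own_stats.unmapped, own_stats.secondary,
        own_stats.duplicate, own_stats.low_quality, own_stats.kept,
    )


def _build_exon_index(model: Sequence[CollapsedGene]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in model:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for exon in gene.exons:
            tree.addi(exon.start, exon.end, gene.locus_id)
    return trees


def count_exonic_reads(
    path: str | Path,
    model: Sequence[CollapsedGene],
    sample_id: str | None = None,
    min_quality: int = DEFAULT_MIN_QUALITY,
    drop_duplicates: bool = True,
    quality_metric: str = "mapping",
) -> SampleCounts:
    """Count cleaned reads overlapping each collapsed gene's exons.

    A read is assigned to a gene when any of its aligned blocks overlaps
    at least one exonic base; a read spanning exons of two genes
    increments both.  G is the number of cleaned mapped reads genome-wide,
    exonic or not.
    """
    if not model:
        raise ValueError("gene model is empty")
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    trees = _build_exon_index(model)
    counts = {g.locus_id: 0 for g in model}
    stats = FilterStats()
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as aln:
        known = set(aln.references or [])
        missing = sorted(set(trees) - known)
        if missing:
            log.warning("chromosomes in model absent from %s header: %s",
                        path.name, ", ".join(missing))
        for read in filter_reads(aln, min_quality, drop_duplicates, stats, quality_metric):
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            hit: set[str] = set()
            for start, end in read.get_blocks():
                for iv in tree.overlap(start, end):
                    hit.add(iv.data)
            for locus_id in hit:
                counts[locus_id] += 1
    return SampleCounts(
        sample_id=sample_id or path.stem,
        counts=counts,
        total_aligned=stats.kept,
        filter_stats=stats,
    )


def compute_spkmg(R: float, E: float, G: float) -> float:
    """SPKMG = 1e9 * R / (E * G); R exonic reads, E exonic bp, G aligned reads."""
    if E <= 0:
        raise ValueError(f"exonic length must be positive, got {E}")
    if G <= 0:
        raise ValueError(f"total aligned reads must be positive, got {G}")
    if R < 0:
        raise ValueError(f"read count must be non-negative, got {R}")
    return SPKMG_SCALE * R / (E * G)


def build_matrix(
    samples: Sequence[SampleCounts], model: Sequence[CollapsedGene]
) -> pd.DataFrame:
    """Assemble the genes x samples SPKMG matrix in genomic gene order."""
    if not samples:
        raise ValueError("no samples")
    order = [g.locus_id for g in model]
    lengths = np.array([g.exonic_length for g in model], dtype=float)
    data = {}
    for sample in samples:
        if sample.total_aligned <= 0:
            raise ValueError(f"sample {sample.sample_id}: no aligned reads (G = 0)")
        r = np.array([sample.counts.get(lid, 0) for lid in order], dtype=float)
        data[sample.sample_id] = SPKMG_SCALE * r / (lengths * sample.total_aligned)
    return pd.DataFrame(data, index=pd.Index(order, name="locus_id"))


def remove_outlier_genes(matrix: pd.DataFrame, gene_symbols: Sequence[str]) -> pd.DataFrame:
    """Drop rows whose gene symbol is listed (e.g. the coverage outlier TTN)."""
    symbols = set(gene_symbols)
    row_symbols = matrix.index.to_series().str.split("|").str[0]
    mask = row_symbols.isin(symbols)
    missing = symbols - set(row_symbols)
    if missing:
        log.warning("outlier symbols not present in matrix: %s", ", ".join(sorted(missing)))
    out = matrix.loc[~mask.to_numpy()]
    if out.empty:
        raise ValueError("removing outlier genes emptied the matrix")
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_qc_table(samples: Sequence[SampleCounts], path: str | Path) -> None:
    rows = []
    for s in samples:
        st = s.filter_stats
        rows.append({
            "sample_id": s.sample_id, "reads_total": st.total,
            "unmapped": st.unmapped, "secondary": st.secondary,
            "duplicate": st.duplicate, "low_quality": st.low_quality,
            "G": s.total_aligned,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
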