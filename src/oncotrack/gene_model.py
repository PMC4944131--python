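"""Collapsed exonic gene model.

Every splice isoform of a gene is merged into a single locus entry whose
exons are the interval union of all isoform exons.  The union's total
length is the exonic length E used to normalize read counts.  All
coordinates are 0-based half-open (BED convention); refFlat exonStarts
are already 0-based, BED12 blocks are converted from relative offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

DEFAULT_LOCUS_GAP = 1_000_000


@dataclass(frozen=True)
class ExonInterval:
    """A single exon: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"exon end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript row (one isoform) from a refFlat or BED12 table."""

    symbol: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)


@dataclass
class CollapsedGene:
    """One gene locus with merged, non-overlapping exon intervals.

    ``exonic_length`` is E: the number of exonic bases of the locus,
    counting each base once however many isoforms cover it.
    """

    symbol: str
    locus_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(f"{self.locus_id}: exons overlap or are unsorted")
        if self.exonic_length <= 0:
            raise ValueError(f"{self.locus_id}: exonic length must be positive")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


class TranscriptParseError(ValueError):
    """Raised for malformed transcript-table rows; carries the line number."""


def _parse_refflat_row(fields: list[str], lineno: int) -> TranscriptRecord:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds
    if len(fields) < 11:
        raise TranscriptParseError(f"line {lineno}: expected 11 refFlat fields, got {len(fields)}")
    symbol, _name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
    try:
        n_exons = int(fields[8])
        starts = [int(s) for s in fields[9].rstrip(",").split(",")]
        ends = [int(s) for s in fields[10].rstrip(",").split(",")]
    except ValueError as exc:
        raise TranscriptParseError(f"line {lineno}: non-integer coordinate ({exc})") from exc
    if len(starts) != n_exons or len(ends) != n_exons:
        raise TranscriptParseError(f"line {lineno}: exonCount does not match exon lists")
    try:
        exons = tuple(
            ExonInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
        )
    except ValueError as exc:
        raise TranscriptParseError(f"line {lineno}: {exc}") from exc
    return TranscriptRecord(symbol=symbol, chrom=chrom, strand=strand, exons=exons)


def _parse_bed12_row(fields: list[str], lineno: int) -> TranscriptRecord:
    if len(fields) < 12:
        raise TranscriptParseError(f"line {lineno}: expected 12 BED12 fields, got {len(fields)}")
    chrom, name, strand = fields[0], fields[3], fields[5]
    try:
        chrom_start = int(fields[1])
        block_count = int(fields[9])
        sizes = [int(s) for s in fields[10].rstrip(",").split(",")]
        offsets = [int(s) for s in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise TranscriptParseError(f"line {lineno}: non-integer field ({exc})") from exc
    if len(sizes) != block_count or len(offsets) != block_count:
        raise TranscriptParseError(f"line {lineno}: blockCount does not match block lists")
    try:
        exons = tuple(
            ExonInterval(chrom, chrom_start + off, chrom_start + off + size, strand)
            for size, off in zip(sizes, offsets)
        )
    except ValueError as exc:
        raise TranscriptParseError(f"line {lineno}: {exc}") from exc
    return TranscriptRecord(symbol=name, chrom=chrom, strand=strand, exons=exons)


_DIALECTS = {"refFlat": _parse_refflat_row, "BED12": _parse_bed12_row}


def load_transcript_table(path: str | Path, dialect: str = "refFlat") -> list[TranscriptRecord]:
    """Read a transcript table, one record per isoform row.

    Parameters
    ----------
    path
        Tab-separated refFlat (UCSC) or BED12 file.
    dialect
        ``"refFlat"`` or ``"BED12"``.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    parse = _DIALECTS[dialect]
    records: list[TranscriptRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            records.append(parse(line.split("\t"), lineno))
    if not records:
        raise TranscriptParseError(f"{path}: no transcript rows found")
    return records


def merge_intervals(
    intervals: Iterable[ExonInterval], merge_adjacent: bool = True
) -> list[ExonInterval]:
    """Union of intervals on a single chromosome; touching intervals merge."""
    ivs = sorted(intervals, key=lambda e: (e.start, e.end))
    if not ivs:
        return []
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        touches = iv.start <= last.end if merge_adjacent else iv.start < last.end
        if touches:
            if iv.end > last.end:
                merged[-1] = ExonInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def collapse_transcripts(
    records: Sequence[TranscriptRecord], locus_gap: int = DEFAULT_LOCUS_GAP
) -> list[CollapsedGene]:
    """Merge isoforms into one entry per gene locus.

    Transcripts sharing a symbol on the same chromosome and strand are
    grouped into loci: isoform spans closer than ``locus_gap`` belong to
    the same locus, so a symbol annotated at two distant positions (or on
    two chromosomes) yields two entries with distinct ``locus_id``s.
    """
    if not records:
        raise ValueError("no transcript records to collapse")
    groups: dict[tuple[str, str, str], list[TranscriptRecord]] = {}
    for rec in records:
        groups.setdefault((rec.symbol, rec.chrom, rec.strand), []).append(rec)

    genes: list[CollapsedGene] = []
    locus_counts: dict[str, int] = {}
    for (symbol, chrom, strand), recs in groups.items():
        recs = sorted(recs, key=lambda r: r.start)
        # split into loci by the gap rule on transcript spans
        loci: list[list[TranscriptRecord]] = [[recs[0]]]
        span_end = recs[0].end
        for rec in recs[1:]:
            if rec.start - span_end > locus_gap:
                loci.append([rec])
            else:
                loci[-1].append(rec)
            span_end = max(span_end, rec.end)
        for locus in loci:
            idx = locus_counts.get(symbol, 0)
            locus_counts[symbol] = idx + 1
            exons = merge_intervals(e for rec in locus for e in rec.exons)
            genes.append(
                CollapsedGene(
                    symbol=symbol,
                    locus_id=f"{symbol}|{chrom}|{idx}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.locus_id))
    return genes


def write_gene_model(genes: Sequence[CollapsedGene], exons_path: str | Path,
                     summary_path: str | Path | None = None) -> None:
    """Write the collapsed model: per-exon BED-like TSV plus a gene summary."""
    with open(exons_path, "w") as out:
        out.write("locus_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            for e in g.exons:
                out.write(f"{g.locus_id}\t{g.chrom}\t{e.start}\t{e.end}\t{g.strand}\n")
    if summary_path is not None:
        with open(summary_path, "w") as out:
            out.write("locus_id\tsymbol\tchrom\tstart\tend\texonic_length\n")
            for g in genes:
                out.write(
                    f"{g.locus_id}\t{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.exonic_length}\n"
                )


def read_gene_model(exons_path: str | Path) -> list[CollapsedGene]:
    """Read the per-exon TSV written by :func:`write_gene_model`."""
    rows: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(exons_path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:4] != ["locus_id", "chrom", "start", "end"]:
            raise ValueError(f"{exons_path}: not a collapsed-model exon table")
        for line in handle:
            locus_id, chrom, start, end, strand = line.rstrip("\n").split("\t")
            rows.setdefault(locus_id, []).append((chrom, int(start), int(end), strand))
    genes = []
    for locus_id, exon_rows in rows.items():
        symbol = locus_id.split("|")[0]
        chrom, strand = exon_rows[0][0], exon_rows[0][3]
        exons = sorted(
            (ExonInterval(c, s, e, st) for c, s, e, st in exon_rows),
            key=lambda iv: iv.start,
        )
        genes.append(CollapsedGene(symbol, locus_id, chrom, strand, exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.locus_id))
    return genes
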