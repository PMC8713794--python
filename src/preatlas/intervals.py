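"""Genomic interval primitives, interval algebra, and plain-text I/O.

Every coordinate in this package is **0-based, half-open** (BED-native):
an interval ``(chrom, start, end)`` covers the bases ``start .. end-1``.
1-based inputs (GFF-style) are *not* supported anywhere; convert before
loading.  Strand is carried on intervals but ignored by all overlap and
merge arithmetic — regulatory elements are strandless.  Only gene TSS
logic respects strand.

Formats handled here: BED6, BEDPE (two anchors plus an FDR column),
bedGraph, and TSV gene-model tables.  All readers validate coordinates
and report malformed lines with their file position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: The five cortical-patterning transcription factors profiled by ChIP-seq.
DEFAULT_TFS = ("EMX2", "LHX2", "NR2F1", "PAX6", "PBX1")

#: Chromatin assays consumed alongside the TF ChIP-seq data.
MARK_ASSAYS = ("ATAC", "H3K27ac", "H3K27me3")

#: Genotype labels for the wild-type and patterning-mutant conditions.
CONDITIONS = ("WT", "Emx2-KO", "Nr2f1-KO", "Pax6-KO")


class ParseError(ValueError):
    """A malformed line in a genomic text file; message carries file:line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PeakCall:
    """A called peak from one assay in one genotype."""

    interval: GenomicInterval
    assay: str
    condition: str = "WT"
    signal: float = 0.0
    summit_offset: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside "
                f"[0, {self.interval.length})"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its transcription start site.

    The TSS must lie inside the (half-open) gene body; by convention it
    sits at the 5' end given the strand, but any in-body position is
    accepted so down-sampled annotations remain loadable.
    """

    gene_id: str
    interval: GenomicInterval
    tss: int
    strand: str = "+"
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.interval.contains(self.tss):
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} outside body "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases.

    Half-open arithmetic: ``[0,10)`` and ``[10,20)`` are adjacent, not
    overlapping.
    """
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    return overlap_length(a, b) >= min_bp


def merge_intervals(
    intervals: Iterable[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals into maximal non-overlapping spans, per chromosome.

    ``min_gap`` is the smallest gap (in bp, half-open) that *prevents*
    merging.  The default 0 merges only intervals sharing >= 1 bp:
    adjacent-but-disjoint intervals (gap 0) stay separate.  ``min_gap=2``
    additionally bridges gaps of 0 or 1 bp.  Merging is transitive: a
    chain of pairwise-overlapping intervals collapses to one span.

    Output is sorted, pairwise non-overlapping, strandless, and (for
    ``min_gap=0``) covers exactly the union of input bases.  Idempotent.
    """
    if min_gap < 0:
        raise ValueError(f"min_gap must be >= 0, got {min_gap}")
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur: Optional[list] = None  # [chrom, start, end]
    for iv in ivs:
        if cur is not None and iv.chrom == cur[0]:
            gap = iv.start - cur[2]
            if gap < min_gap or gap < 0:
                cur[2] = max(cur[2], iv.end)
                continue
        if cur is not None:
            merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
        cur = [iv.chrom, iv.start, iv.end]
    if cur is not None:
        merged.append(GenomicInterval(cur[0], cur[1], cur[2]))
    return merged


def distance_to_tss(interval: GenomicInterval, gene: GeneModel) -> Optional[int]:
    """Distance in bp from an interval to a gene's TSS.

    Returns 0 when the TSS base lies inside the interval, otherwise the
    nearest-edge distance ``min(|start - tss|, |end - 1 - tss|)``.
    Cross-chromosome pairs have no defined distance and return ``None``
    (the "unlinked" sentinel, distinct from every integer).
    """
    if interval.chrom != gene.chrom:
        return None
    tss = gene.tss
    if interval.contains(tss):
        return 0
    return min(abs(interval.start - tss), abs(interval.end - 1 - tss))


class IntervalIndex:
    """Overlap index over (interval, payload) pairs, per chromosome.

    Thin wrapper around :mod:`intervaltree` preserving half-open
    semantics; used for all join-style queries in the pipeline.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, Any]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for iv, payload in items:
            self.add(iv, payload)

    def add(self, iv: GenomicInterval, payload: Any) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, (iv, payload)
        )

    def overlapping(
        self, query: GenomicInterval, min_bp: int = 1
    ) -> list[tuple[GenomicInterval, Any]]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = []
        for node in sorted(tree.overlap(query.start, query.end)):
            iv, payload = node.data
            if overlap_length(iv, query) >= min_bp:
                hits.append((iv, payload))
        return hits

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph)
# ---------------------------------------------------------------------------

class CoverageTrack:
    """Step-function coverage over a genome, as read from bedGraph.

    Steps must be sorted and non-overlapping within each chromosome,
    with depth >= 0.  ``library_size`` is a total-mapped-reads proxy used
    for RPM normalization; when not supplied it defaults to the total
    base-coverage sum(depth * width), which is proportional to read
    count for fixed read length.
    """

    def __init__(
        self,
        steps: Iterable[tuple[GenomicInterval, float]],
        library_size: Optional[float] = None,
    ) -> None:
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, depth in steps:
            if depth < 0:
                raise ValueError(f"coverage depth must be >= 0, got {depth}")
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(depth)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._depths: dict[str, np.ndarray] = {}
        total = 0.0
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            depths = np.array([r[2] for r in rows], dtype=float)
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping coverage steps on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._depths[chrom] = depths
            total += float(np.sum(depths * (ends - starts)))
        if library_size is not None and library_size <= 0:
            raise ValueError(f"library_size must be positive, got {library_size}")
        self.library_size = float(library_size) if library_size else total
        self.total_coverage = total

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._starts)

    def steps(self) -> Iterator[tuple[GenomicInterval, float]]:
        for chrom in self.chromosomes:
            for s, e, d in zip(
                self._starts[chrom], self._ends[chrom], self._depths[chrom]
            ):
                yield GenomicInterval(chrom, int(s), int(e)), float(d)

    def mean_depth(self, interval: GenomicInterval) -> float:
        """Mean per-base depth over ``interval`` (absent bases count 0)."""
        chrom = interval.chrom
        if chrom not in self._starts:
            raise KeyError(
                f"chromosome {chrom!r} absent from coverage track "
                f"(has {self.chromosomes})"
            )
        starts, ends, depths = self._starts[chrom], self._ends[chrom], self._depths[chrom]
        lo = np.searchsorted(ends, interval.start, side="right")
        hi = np.searchsorted(starts, interval.end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], interval.start)
        e = np.minimum(ends[lo:hi], interval.end)
        covered = np.sum(depths[lo:hi] * np.maximum(0, e - s))
        return float(covered) / interval.length

    def mean_rpm(self, interval: GenomicInterval) -> float:
        """Mean depth over ``interval`` scaled to reads-per-million."""
        return self.mean_depth(interval) * 1e6 / self.library_size


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    """One BED6 line: an interval plus its name and score columns."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0


def _open(path: Union[str, Path, io.TextIOBase], mode: str = "r"):
    if isinstance(path, io.TextIOBase):
        return path, False
    return open(path, mode), True


def _parse_coords(fields: Sequence[str], path: str, lineno: int) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate: {exc}") from None
    if start < 0:
        raise ParseError(f"{path}:{lineno}: negative start {start}")
    if end <= start:
        raise ParseError(f"{path}:{lineno}: end {end} <= start {start}")
    return chrom, start, end


def read_bed(path: Union[str, Path]) -> list[BedRecord]:
    """Read a BED3/BED6 file (0-based half-open) into :class:`BedRecord`s."""
    records = []
    fh, close = _open(path)
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = _parse_coords(fields, str(path), lineno)
            name = fields[3] if len(fields) > 3 else "."
            score = 0.0
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            records.append(
                BedRecord(GenomicInterval(chrom, start, end, strand), name, score)
            )
    finally:
        if close:
            fh.close()
    return records


def write_bed(path: Union[str, Path], records: Iterable[Union[BedRecord, GenomicInterval]]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rec = BedRecord(rec)
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{rec.score:g}\t{iv.strand}\n"
            )


def read_peaks_bed(
    path: Union[str, Path], assay: str, condition: str = "WT"
) -> list[PeakCall]:
    """Read a BED6 peak file, tagging every record with assay/condition."""
    return [
        PeakCall(rec.interval, assay=assay, condition=condition,
                 signal=rec.score, name=rec.name)
        for rec in read_bed(path)
    ]


def read_bedpe(path: Union[str, Path]) -> list[tuple[GenomicInterval, GenomicInterval, float]]:
    """Read BEDPE anchor pairs with a significance (FDR) column 7."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 7 columns (two anchors + FDR)"
                )
            c1, s1, e1 = _parse_coords(fields[0:3], str(path), lineno)
            c2, s2, e2 = _parse_coords(fields[3:6], str(path), lineno)
            try:
                fdr = float(fields[6])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric FDR {fields[6]!r}"
                ) from None
            out.append(
                (GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2), fdr)
            )
    return out


def write_bedpe(
    path: Union[str, Path],
    pairs: Iterable[tuple[GenomicInterval, GenomicInterval, float]],
) -> None:
    with open(path, "w") as fh:
        for a1, a2, fdr in pairs:
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t"
                f"{a2.chrom}\t{a2.start}\t{a2.end}\t{fdr:.6g}\n"
            )


def read_bedgraph(
    path: Union[str, Path], library_size: Optional[float] = None
) -> CoverageTrack:
    steps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end = _parse_coords(fields, str(path), lineno)
            try:
                depth = float(fields[3])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric depth {fields[3]!r}"
                ) from None
            if depth < 0:
                raise ParseError(f"{path}:{lineno}: negative depth {depth}")
            steps.append((GenomicInterval(chrom, start, end), depth))
    return CoverageTrack(steps, library_size=library_size)


def write_bedgraph(
    path: Union[str, Path], track: CoverageTrack, include_zero: bool = False
) -> None:
    with open(path, "w") as fh:
        for iv, depth in track.steps():
            if depth == 0 and not include_zero:
                continue
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{depth:.6g}\n")


def read_gene_table(path: Union[str, Path]) -> list[GeneModel]:
    """Read a TSV gene-model table.

    Expected columns (header required):
    ``gene_id  chrom  start  end  strand  tss`` with an optional ``name``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene table missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
                tss=int(row.tss),
                strand=str(row.strand),
                name=str(getattr(row, "name_", getattr(row, "name", row.gene_id))),
            )
        )
    return genes


def write_gene_table(path: Union[str, Path], genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\ttss\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.strand}\t{g.tss}\n"
            )


def read_table(path: Union[str, Path], **kwargs):
    """Generic TSV reader (pandas) for label/sidecar tables."""
    import pandas as pd

    kwargs.setdefault("sep", "\t")
    return pd.read_csv(path, **kwargs)
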