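"""Putative regulatory element (pRE) catalog construction.

A pRE is a maximal span of overlapping TF ChIP-seq peaks from the
wild-type condition.  Each pRE carries an occupancy vector over the
configured TF registry (default EMX2, LHX2, NR2F1, PAX6, PBX1): a TF
"binds" the pRE iff at least one of its peaks overlaps it by >= 1 bp,
which — because the pRE is built from those same peaks — is equivalent
to having contributed a source peak.  The occupancy count (1..5 for
catalog pREs; 0 is reserved for externally supplied elements such as
assayed enhancers with no TF peak) is the combinatorial binding class
used throughout the downstream analyses.

Peak heights are made comparable across TFs by reads-per-million
scaling followed by within-TF percentile midranks, so each TF's signal
distribution is mapped onto [0, 100] regardless of coverage depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .intervals import (
    DEFAULT_TFS,
    GenomicInterval,
    IntervalIndex,
    PeakCall,
    merge_intervals,
    overlap_length,
)


@dataclass(frozen=True)
class OccupancyVector:
    """Which TFs bind an element; ``count`` is the combinatorial class."""

    bound: Mapping[str, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound", dict(self.bound))

    @property
    def count(self) -> int:
        return sum(bool(v) for v in self.bound.values())

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(sorted(tf for tf, v in self.bound.items() if v))

    def __getitem__(self, tf: str) -> bool:
        return self.bound[tf]


@dataclass(frozen=True)
class PutativeRegulatoryElement:
    """A merged TF-binding span with its occupancy and signal ranks."""

    pre_id: str
    interval: GenomicInterval
    occupancy: OccupancyVector
    signal_rank: Mapping[str, float] = field(default_factory=dict)
    source_peaks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal_rank", dict(self.signal_rank))
        object.__setattr__(self, "source_peaks", tuple(self.source_peaks))
        extra = set(self.signal_rank) - {
            tf for tf, v in self.occupancy.bound.items() if v
        }
        if extra:
            raise ValueError(f"signal ranks for unbound TFs: {sorted(extra)}")


def normalize_signal(
    tf_peaks: Mapping[str, Sequence[PeakCall]],
    library_sizes: Mapping[str, float],
) -> dict[str, list[PeakCall]]:
    """Depth-normalize peak heights and convert to within-TF percentiles.

    Each peak's raw signal is scaled to reads-per-million
    (``signal * 1e6 / library_size``) and then replaced by its percentile
    midrank within that TF's peak set: ``(rank - 0.5) / n * 100`` with
    average ranks for ties.  A singleton peak therefore gets 50.  Ranks
    are invariant to any per-TF monotone rescaling of the raw signal,
    which is the point: they remove coverage-depth differences between
    the TF ChIP-seq libraries.
    """
    out: dict[str, list[PeakCall]] = {}
    for tf, peaks in tf_peaks.items():
        if tf not in library_sizes:
            raise ValueError(f"no library size supplied for {tf}")
        lib = library_sizes[tf]
        if lib <= 0:
            raise ValueError(f"library size for {tf} must be positive, got {lib}")
        peaks = list(peaks)
        if not peaks:
            out[tf] = []
            continue
        rpm = np.array([p.signal for p in peaks], dtype=float) * 1e6 / lib
        ranks = (rankdata(rpm, method="average") - 0.5) / len(rpm) * 100.0
        out[tf] = [
            PeakCall(
                interval=p.interval,
                assay=p.assay,
                condition=p.condition,
                signal=float(r),
                summit_offset=p.summit_offset,
                name=p.name,
            )
            for p, r in zip(peaks, ranks)
        ]
    return out


def call_pres(
    tf_peaks: Mapping[str, Sequence[PeakCall]],
    min_gap: int = 0,
    id_prefix: str = "pRE",
) -> list[PutativeRegulatoryElement]:
    """Merge overlapping WT TF peaks into the pRE catalog.

    Every input peak base is covered by exactly one pRE (the catalog
    partitions the per-base union of all TF peaks).  Each pRE records
    the TFs that contributed >= 1 overlapping peak, the maximum signal
    per bound TF (percentile ranks if :func:`normalize_signal` was
    applied upstream), and its source peak names.

    Only wild-type peaks may enter the catalog: the WT catalog is the
    fixed universe against which mutant chromatin is later compared, so
    mutant peak sets are rejected here.
    """
    if not tf_peaks or not any(len(v) for v in tf_peaks.values()):
        raise ValueError("call_pres requires at least one TF with >= 1 peak")
    all_peaks: list[tuple[str, PeakCall]] = []
    for tf, peaks in tf_peaks.items():
        for p in peaks:
            if p.condition != "WT":
                raise ValueError(
                    f"catalog construction accepts WT peaks only; got "
                    f"condition {p.condition!r} for {tf}"
                )
            all_peaks.append((tf, p))

    merged = merge_intervals((p.interval for _, p in all_peaks), min_gap=min_gap)
    index = IntervalIndex()
    members: dict[int, list[tuple[str, PeakCall]]] = {i: [] for i in range(len(merged))}
    for i, span in enumerate(merged):
        index.add(span, i)
    for tf, p in all_peaks:
        hits = index.overlapping(p.interval)
        if not hits:  # pragma: no cover - every peak lies in a merged span
            raise AssertionError("peak escaped its merged span")
        for _, i in hits:
            members[i].append((tf, p))

    registry = tuple(tf_peaks)
    width = max(4, len(str(len(merged))))
    pres = []
    for i, span in enumerate(merged):
        bound = {tf: False for tf in registry}
        ranks: dict[str, float] = {}
        names = []
        for tf, p in members[i]:
            bound[tf] = True
            if tf not in ranks or p.signal > ranks[tf]:
                ranks[tf] = p.signal
            names.append(p.name or f"{tf}:{p.interval.chrom}:{p.interval.start}")
        pres.append(
            PutativeRegulatoryElement(
                pre_id=f"{id_prefix}{i + 1:0{width}d}",
                interval=span,
                occupancy=OccupancyVector(bound),
                signal_rank=ranks,
                source_peaks=tuple(names),
            )
        )
    return pres


def occupancy_spectrum(
    pres: Iterable[PutativeRegulatoryElement], n_tfs: int = len(DEFAULT_TFS)
) -> dict[int, int]:
    """Tabulate the catalog by combinatorial binding class (0..n_tfs).

    Classes 1..n partition a TF-derived catalog; class 0 is populated
    only when externally supplied (e.g. unbound assayed enhancers) are
    included.  Counts sum to the number of elements given.
    """
    spectrum = {k: 0 for k in range(n_tfs + 1)}
    for pre in pres:
        spectrum[pre.occupancy.count] += 1
    return spectrum


def write_catalog(path, pres: Sequence[PutativeRegulatoryElement], tfs: Sequence[str] = DEFAULT_TFS) -> None:
    """Write the catalog as BED6+ with occupancy and per-TF rank columns."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tpre_id\toccupancy_count\tstrand\tbound_tfs\t"
            + "\t".join(f"rank_{tf}" for tf in tfs)
            + "\n"
        )
        for pre in pres:
            iv = pre.interval
            ranks = "\t".join(
                f"{pre.signal_rank[tf]:.3f}" if pre.occupancy.bound.get(tf) and tf in pre.signal_rank else "NA"
                for tf in tfs
            )
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pre.pre_id}\t"
                f"{pre.occupancy.count}\t.\t{','.join(pre.occupancy.tfs) or '.'}\t{ranks}\n"
            )


def read_catalog(path, tfs: Sequence[str] = DEFAULT_TFS) -> list[PutativeRegulatoryElement]:
    """Read a catalog written by :func:`write_catalog`."""
    pres = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").split()
        rank_cols = [c[len("rank_"):] for c in header if c.startswith("rank_")]
        for line in fh:
            f = line.split()
            chrom, start, end, pre_id = f[0], int(f[1]), int(f[2]), f[3]
            bound_tfs = set() if f[6] == "." else set(f[6].split(","))
            bound = {tf: tf in bound_tfs for tf in (rank_cols or tfs)}
            ranks = {
                tf: float(v)
                for tf, v in zip(rank_cols, f[7:])
                if v != "NA"
            }
            pres.append(
                PutativeRegulatoryElement(
                    pre_id=pre_id,
                    interval=GenomicInterval(chrom, start, end),
                    occupancy=OccupancyVector(bound),
                    signal_rank=ranks,
                )
            )
    return pres
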