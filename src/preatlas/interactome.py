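"""Gene locus windows and pRE-to-gene assignment from chromatin loops.

A gene's cis-regulatory interactome is assembled from three evidence
classes:

* ``loop5k`` / ``loop10k`` — significant promoter-anchored bin-pair
  interactions (PLAC-seq style), pre-filtered at FDR < 0.01.  A loop
  links a pRE to a gene iff one anchor overlaps the promoter bin (the
  fixed-resolution bin containing the TSS) and the other anchor
  overlaps the pRE by >= 1 bp.
* ``computational`` — precomputed pRE-gene associations supplied as a
  two-column table; consumed, never recomputed.
* ``window`` — membership in the gene-body window extended by 100 kb on
  each side, further extended to the most distal loop contact.

Evidence tags are accumulated per member, so a looped pRE inside the
window carries both tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import (
    GeneModel,
    GenomicInterval,
    IntervalIndex,
    distance_to_tss,
    overlap_length,
)
from .catalog import PutativeRegulatoryElement

LOOP_RESOLUTIONS = (5000, 10000)


@dataclass(frozen=True)
class BinPairInteraction:
    """A significant loop between two fixed-resolution genomic bins."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    fdr: float

    def __post_init__(self) -> None:
        if self.resolution not in LOOP_RESOLUTIONS:
            raise ValueError(
                f"loop resolution must be one of {LOOP_RESOLUTIONS}, "
                f"got {self.resolution}"
            )
        for a in (self.anchor1, self.anchor2):
            if a.length != self.resolution:
                raise ValueError(
                    f"anchor {a.chrom}:{a.start}-{a.end} length != resolution "
                    f"{self.resolution}"
                )
            if a.start % self.resolution != 0:
                raise ValueError(
                    f"anchor start {a.start} not aligned to {self.resolution}-bp bins"
                )
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR must be in [0,1], got {self.fdr}")


@dataclass
class GeneLocus:
    """A gene with its locus window and evidence-tagged member pREs."""

    gene: GeneModel
    window: GenomicInterval
    members: dict[str, set[str]] = field(default_factory=dict)  # pre_id -> tags

    @property
    def member_pre_ids(self) -> list[str]:
        return sorted(self.members)


def loops_from_bedpe(
    pairs: Iterable[tuple[GenomicInterval, GenomicInterval, float]],
    resolution: int,
    fdr_threshold: float = 0.01,
) -> list[BinPairInteraction]:
    """Build loop objects from BEDPE rows, applying the FDR filter."""
    loops = []
    for a1, a2, fdr in pairs:
        if fdr < fdr_threshold:
            loops.append(BinPairInteraction(a1, a2, resolution=resolution, fdr=fdr))
    return loops


def promoter_bin(gene: GeneModel, resolution: int, slop_bins: int = 0) -> GenomicInterval:
    """The fixed-resolution bin containing the TSS (+- ``slop_bins`` bins)."""
    start = (gene.tss // resolution - slop_bins) * resolution
    end = (gene.tss // resolution + 1 + slop_bins) * resolution
    return GenomicInterval(gene.chrom, max(0, start), end)


def _loop_contacts(
    gene: GeneModel,
    loops: Sequence[BinPairInteraction],
    resolution: int,
    promoter_slop_bins: int = 0,
) -> list[tuple[GenomicInterval, BinPairInteraction]]:
    """Non-promoter anchors of loops whose other anchor hits the TSS bin."""
    pbin = promoter_bin(gene, resolution, promoter_slop_bins)
    contacts = []
    for loop in loops:
        if loop.resolution != resolution:
            raise ValueError(
                f"loop at {loop.resolution}-bp resolution in a "
                f"{resolution}-bp analysis"
            )
        hit1 = overlap_length(loop.anchor1, pbin) >= 1
        hit2 = overlap_length(loop.anchor2, pbin) >= 1
        if hit1:
            contacts.append((loop.anchor2, loop))
        if hit2 and not hit1:
            contacts.append((loop.anchor1, loop))
    return contacts


def build_locus(
    gene: GeneModel,
    loops: Sequence[BinPairInteraction],
    pres: Sequence[PutativeRegulatoryElement],
    computational_links: Optional[Mapping[str, Iterable[str]]] = None,
    window_bp: int = 100_000,
    resolution: int = 5000,
    promoter_slop_bins: int = 0,
    pre_index: Optional[IntervalIndex] = None,
) -> GeneLocus:
    """Assemble one gene's locus window and member pREs.

    The window is the union of the gene body extended by ``window_bp``
    on each side and the span out to the farthest loop contact; loop
    evidence can therefore only grow a locus.  ``computational_links``
    maps gene_id -> pre_ids and is evidence-tagged as supplied.
    """
    if pre_index is None:
        pre_index = IntervalIndex((p.interval, p) for p in pres)
    by_id = {p.pre_id: p for p in pres}

    tag = f"loop{resolution // 1000}k"
    contacts = _loop_contacts(gene, loops, resolution, promoter_slop_bins)

    body = gene.interval
    win_start = max(0, body.start - window_bp)
    win_end = body.end + window_bp
    for anchor, _ in contacts:
        if anchor.chrom == gene.chrom:
            win_start = min(win_start, anchor.start)
            win_end = max(win_end, anchor.end)
    window = GenomicInterval(gene.chrom, win_start, win_end)

    members: dict[str, set[str]] = {}

    def add(pre_id: str, evidence: str) -> None:
        members.setdefault(pre_id, set()).add(evidence)

    for anchor, _ in contacts:
        for _, pre in pre_index.overlapping(anchor):
            add(pre.pre_id, tag)
    if computational_links:
        for pre_id in computational_links.get(gene.gene_id, ()):  # type: ignore[union-attr]
            if pre_id not in by_id:
                raise ValueError(
                    f"computational link for {gene.gene_id} names unknown pRE "
                    f"{pre_id!r}"
                )
            add(pre_id, "computational")
    for _, pre in pre_index.overlapping(window):
        add(pre.pre_id, "window")

    return GeneLocus(gene=gene, window=window, members=members)


def build_interactome(
    genes: Sequence[GeneModel],
    loops: Sequence[BinPairInteraction],
    pres: Sequence[PutativeRegulatoryElement],
    computational_links: Optional[Mapping[str, Iterable[str]]] = None,
    window_bp: int = 100_000,
    resolution: int = 5000,
    promoter_slop_bins: int = 0,
) -> dict[str, GeneLocus]:
    """:func:`build_locus` over a gene annotation, sharing one pRE index."""
    index = IntervalIndex((p.interval, p) for p in pres)
    return {
        g.gene_id: build_locus(
            g, loops, pres,
            computational_links=computational_links,
            window_bp=window_bp,
            resolution=resolution,
            promoter_slop_bins=promoter_slop_bins,
            pre_index=index,
        )
        for g in genes
    }


def distal_fraction(
    loops: Sequence[BinPairInteraction],
    genes: Sequence[GeneModel],
    min_distal_bp: int = 2500,
    resolution: Optional[int] = None,
    promoter_slop_bins: int = 0,
) -> float:
    """Fraction of promoter-linked interactions that are distal.

    An interaction is one (loop, gene) pairing in which an anchor
    overlaps the gene's TSS bin.  It counts as distal when the nearest
    edge of the *other* anchor is at least ``min_distal_bp`` from the
    TSS ("at least": the boundary is inclusive).  Loops touching no
    promoter bin do not enter the denominator.
    """
    if not loops:
        raise ValueError("distal_fraction requires >= 1 loop")
    n_links = 0
    n_distal = 0
    for gene in genes:
        res = resolution or loops[0].resolution
        for anchor, _ in _loop_contacts(gene, loops, res, promoter_slop_bins):
            d = distance_to_tss(anchor, gene)
            if d is None:
                continue
            n_links += 1
            if d >= min_distal_bp:
                n_distal += 1
    if n_links == 0:
        raise ValueError("no loop touches any promoter bin")
    return n_distal / n_links


def count_gene_links(
    loci: Mapping[str, GeneLocus],
    pres: Sequence[PutativeRegulatoryElement],
    min_occupancy: int,
    evidence: Optional[Sequence[str]] = None,
) -> tuple[dict[str, bool], int]:
    """Per-gene: has the locus >= 1 member pRE of the given occupancy?

    Returns the per-gene boolean map and the tally of satisfied genes.
    ``evidence`` restricts membership to the listed tags (default: all).
    """
    if not 1 <= min_occupancy:
        raise ValueError(f"min_occupancy must be >= 1, got {min_occupancy}")
    by_id = {p.pre_id: p for p in pres}
    result: dict[str, bool] = {}
    for gene_id, locus in loci.items():
        ok = False
        for pre_id, tags in locus.members.items():
            if evidence is not None and not tags.intersection(evidence):
                continue
            if by_id[pre_id].occupancy.count >= min_occupancy:
                ok = True
                break
        result[gene_id] = ok
    return result, sum(result.values())


def write_interactome(path, loci: Mapping[str, GeneLocus], pres: Sequence[PutativeRegulatoryElement]) -> None:
    """Locus membership as TSV (gene_id, pre_id, evidence, distance_to_tss)."""
    by_id = {p.pre_id: p for p in pres}
    with open(path, "w") as fh:
        fh.write("gene_id\tpre_id\tevidence\tdistance_to_tss\n")
        for gene_id in sorted(loci):
            locus = loci[gene_id]
            for pre_id in locus.member_pre_ids:
                d = distance_to_tss(by_id[pre_id].interval, locus.gene)
                fh.write(
                    f"{gene_id}\t{pre_id}\t{','.join(sorted(locus.members[pre_id]))}\t"
                    f"{'NA' if d is None else d}\n"
                )
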