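"""Permutation null for gene-network regulatory enrichment.

The question: are combinatorially bound distal pREs found near the
TSSs of a gene network more often than near random gene sets of the
same size?  A gene "satisfies" the criterion when at least one pRE
bound by >= ``min_occupancy`` TFs (default 3) lies at a distal distance
from its TSS — nearest-edge distance in [2,500 bp, 100 kb], both ends
inclusive.  The null draws ``n_perm`` (default 1,000) uniform samples
of the network's size from the full gene universe (network genes are
*not* excluded from the pool; an option removes them) and counts
satisfying genes per draw.

Fold enrichment is the observed proportion over the null-median
proportion; the empirical p-value uses the add-one convention
(1 + #{null >= observed}) / (n_perm + 1), which can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import PutativeRegulatoryElement
from .intervals import GeneModel, IntervalIndex, distance_to_tss
from .reporting import fold_one_decimal, format_fold, percent_int


def gene_satisfies(
    gene: GeneModel,
    pres: Sequence[PutativeRegulatoryElement],
    min_occupancy: int = 3,
    max_dist: int = 100_000,
    min_dist_distal: int = 2500,
    pre_index: Optional[IntervalIndex] = None,
) -> bool:
    """True iff a >= ``min_occupancy``-bound pRE sits distally near the TSS.

    Distal means nearest-edge TSS distance in
    ``[min_dist_distal, max_dist]`` (inclusive): a high-occupancy pRE
    1 kb from the TSS is proximal and does not count.
    """
    if pre_index is not None:
        from .intervals import GenomicInterval

        lo = max(0, gene.tss - max_dist)
        window = GenomicInterval(gene.chrom, lo, gene.tss + max_dist + 1)
        candidates = [p for _, p in pre_index.overlapping(window)]
    else:
        candidates = [p for p in pres if p.interval.chrom == gene.chrom]
    for pre in candidates:
        if pre.occupancy.count < min_occupancy:
            continue
        d = distance_to_tss(pre.interval, gene)
        if d is not None and min_dist_distal <= d <= max_dist:
            return True
    return False


def satisfying_genes(
    genes: Sequence[GeneModel],
    pres: Sequence[PutativeRegulatoryElement],
    min_occupancy: int = 3,
    max_dist: int = 100_000,
    min_dist_distal: int = 2500,
) -> dict[str, bool]:
    """Vectorized :func:`gene_satisfies` over an annotation."""
    index = IntervalIndex((p.interval, p) for p in pres)
    return {
        g.gene_id: gene_satisfies(
            g, pres, min_occupancy, max_dist, min_dist_distal, pre_index=index
        )
        for g in genes
    }


@dataclass
class EnrichmentResult:
    """Outcome of the random-gene-set permutation test."""

    observed_count: int
    set_size: int
    null_counts: np.ndarray
    seed: int
    n_universe: int

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=int)
        if not 0 <= self.observed_count <= self.set_size:
            raise ValueError("observed_count outside [0, set_size]")

    @property
    def n_perm(self) -> int:
        return len(self.null_counts)

    @property
    def null_median(self) -> float:
        # even-length nulls: midpoint average, numpy's default
        return float(np.median(self.null_counts))

    @property
    def fold(self) -> float:
        """Observed proportion over null-median proportion (unrounded)."""
        if self.null_median == 0:
            return float("inf")
        return self.observed_count / self.null_median

    @property
    def fold_rounded(self) -> float:
        return fold_one_decimal(self.observed_count, self.null_median)

    @property
    def empirical_p(self) -> float:
        """Add-one permutation p: (1 + #{null >= obs}) / (n_perm + 1)."""
        return float(
            (1 + np.sum(self.null_counts >= self.observed_count))
            / (self.n_perm + 1)
        )

    def summary(self) -> str:
        obs_pct = percent_int(self.observed_count, self.set_size)
        med = self.null_median
        med_str = f"{med:g}"
        med_pct = percent_int(med, self.set_size)
        return (
            f"{self.observed_count}/{self.set_size} ({obs_pct}%) network genes "
            f"with combinatorial distal pREs vs null median {med_str}/"
            f"{self.set_size} ({med_pct}%): {format_fold(self.fold_rounded)} "
            f"enrichment, empirical P = {self.empirical_p:.4g} "
            f"({self.n_perm} permutations, seed {self.seed})"
        )

    def to_dict(self) -> dict:
        return {
            "observed_count": int(self.observed_count),
            "set_size": int(self.set_size),
            "observed_pct": percent_int(self.observed_count, self.set_size),
            "null_median": self.null_median,
            "null_median_pct": percent_int(self.null_median, self.set_size),
            "fold": self.fold,
            "fold_rounded": self.fold_rounded,
            "empirical_p": self.empirical_p,
            "n_perm": self.n_perm,
            "n_universe": self.n_universe,
            "seed": int(self.seed),
        }


def permutation_test(
    network_genes: Sequence[str],
    all_genes: Sequence[str],
    satisfies: Mapping[str, bool],
    n_perm: int = 1000,
    seed: int = 0,
    exclude_network: bool = False,
) -> EnrichmentResult:
    """Observed satisfying-gene count vs ``n_perm`` random same-size sets.

    ``satisfies`` maps gene_id -> bool (see :func:`satisfying_genes`).
    The sampling pool is the full universe including the network genes
    unless ``exclude_network``.  Deterministic given ``seed``.
    """
    network = list(dict.fromkeys(network_genes))
    universe = list(dict.fromkeys(all_genes))
    missing = [g for g in network if g not in set(universe)]
    if missing:
        raise ValueError(f"network genes absent from universe: {missing[:5]}")
    for g in universe:
        if g not in satisfies:
            raise ValueError(f"gene {g!r} missing from the satisfies map")
    pool = (
        [g for g in universe if g not in set(network)]
        if exclude_network
        else universe
    )
    k = len(network)
    if len(pool) <= k:
        raise ValueError(
            f"sampling pool ({len(pool)} genes) must exceed set size {k}"
        )
    sat = np.array([satisfies[g] for g in pool], dtype=bool)
    observed = sum(satisfies[g] for g in network)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    n = len(pool)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        null_counts[i] = int(sat[idx].sum())

    return EnrichmentResult(
        observed_count=int(observed),
        set_size=k,
        null_counts=null_counts,
        seed=seed,
        n_universe=len(universe),
    )
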