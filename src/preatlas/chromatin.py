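"""Chromatin state over the pRE catalog.

Overlays ATAC (accessibility), H3K27ac (active), and H3K27me3
(repressed) peak sets on the fixed WT pRE catalog.  The three flags are
independent — a pRE may be simultaneously active- and repressed-marked
(bivalent-style calls are permitted; marks are tabulated separately).

The locus-level activity metric is the acetylation/methylation ratio:
per gene locus, (#active members + a) / (#repressed members + a) with
pseudocount a (default 0.5) so empty denominators stay finite.  The
medial-pallium comparison is an unpaired two-tailed t-test between MP
and non-MP gene groups, performed on log-ratios for variance
stabilization (raw-ratio mode available); group means of raw ratios
and pooled-count ratios are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PutativeRegulatoryElement
from .interactome import GeneLocus
from .intervals import MARK_ASSAYS, IntervalIndex, PeakCall


@dataclass(frozen=True)
class ChromatinStateCall:
    """Per-pRE mark flags in one condition."""

    pre_id: str
    accessible: bool
    active: bool
    repressed: bool
    condition: str = "WT"

    def flag(self, mark: str) -> bool:
        return {
            "ATAC": self.accessible,
            "H3K27ac": self.active,
            "H3K27me3": self.repressed,
        }[mark]


@dataclass(frozen=True)
class LocusRatio:
    """Per-locus acetylation/methylation ratio with its group label."""

    gene_id: str
    n_active_pres: int
    n_repressed_pres: int
    ratio: float
    group: str  # "MP" | "non-MP"


def call_states(
    pres: Sequence[PutativeRegulatoryElement],
    mark_peaks: Mapping[str, Sequence[PeakCall]],
    condition: str = "WT",
) -> list[ChromatinStateCall]:
    """Flag each pRE by >= 1 bp overlap with each mark's peaks."""
    unknown = set(mark_peaks) - set(MARK_ASSAYS)
    if unknown:
        raise ValueError(
            f"unknown assay names {sorted(unknown)}; expected subset of "
            f"{MARK_ASSAYS}"
        )
    indexes = {
        mark: IntervalIndex((p.interval, p) for p in peaks)
        for mark, peaks in mark_peaks.items()
    }
    calls = []
    for pre in pres:
        hit = {
            mark: bool(idx.overlapping(pre.interval))
            for mark, idx in indexes.items()
        }
        calls.append(
            ChromatinStateCall(
                pre_id=pre.pre_id,
                accessible=hit.get("ATAC", False),
                active=hit.get("H3K27ac", False),
                repressed=hit.get("H3K27me3", False),
                condition=condition,
            )
        )
    return calls


def mark_by_occupancy(
    states: Sequence[ChromatinStateCall],
    pres: Sequence[PutativeRegulatoryElement],
    extra_class0: Optional[Sequence[ChromatinStateCall]] = None,
) -> pd.DataFrame:
    """Percent of pREs carrying each mark, by combinatorial class.

    Rows are occupancy classes (0..5) present in the input; columns are
    the three marks.  Class 0 appears only via ``extra_class0``
    (state calls for externally supplied unbound elements).  Classes
    with zero members are omitted with a warning.
    """
    count_by_id = {p.pre_id: p.occupancy.count for p in pres}
    rows: dict[int, dict[str, list[bool]]] = {}
    for call in states:
        if call.pre_id not in count_by_id:
            raise ValueError(f"state call for unknown pRE {call.pre_id!r}")
        k = count_by_id[call.pre_id]
        bucket = rows.setdefault(k, {m: [] for m in MARK_ASSAYS})
        for m in MARK_ASSAYS:
            bucket[m].append(call.flag(m))
    if extra_class0:
        bucket = rows.setdefault(0, {m: [] for m in MARK_ASSAYS})
        for call in extra_class0:
            for m in MARK_ASSAYS:
                bucket[m].append(call.flag(m))

    n_tfs = max((p.occupancy.count for p in pres), default=0)
    for k in range(n_tfs + 1):
        if k not in rows and k > 0:
            warnings.warn(f"occupancy class {k} has no pREs; row omitted")
    table = {
        k: {m: 100.0 * np.mean(v[m]) for m in MARK_ASSAYS}
        for k, v in sorted(rows.items())
    }
    df = pd.DataFrame.from_dict(table, orient="index")
    df.index.name = "occupancy"
    return df


def locus_ratios(
    loci: Mapping[str, GeneLocus],
    states: Sequence[ChromatinStateCall],
    mp_genes: Iterable[str],
    pseudocount: float = 0.5,
) -> list[LocusRatio]:
    """Acetylation/methylation ratio per gene locus.

    Counts member pREs flagged active (H3K27ac) and repressed
    (H3K27me3); ratio = (n_active + a)/(n_repressed + a).  Loci with no
    member pREs are skipped.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    by_id = {c.pre_id: c for c in states}
    mp = set(mp_genes)
    out = []
    for gene_id in sorted(loci):
        locus = loci[gene_id]
        members = [by_id[p] for p in locus.member_pre_ids if p in by_id]
        if not members:
            continue
        n_act = sum(c.active for c in members)
        n_rep = sum(c.repressed for c in members)
        out.append(
            LocusRatio(
                gene_id=gene_id,
                n_active_pres=n_act,
                n_repressed_pres=n_rep,
                ratio=(n_act + pseudocount) / (n_rep + pseudocount),
                group="MP" if gene_id in mp else "non-MP",
            )
        )
    return out


def compare_groups(
    ratios: Sequence[LocusRatio],
    log_scale: bool = True,
) -> dict:
    """Unpaired two-tailed t-test of MP vs non-MP locus ratios.

    Performed on log-ratios by default; reports raw group means, the
    pooled-count ratio per group, and the t-test p-value.  Degenerate
    cases (an empty group, or zero variance in both groups) are
    reported with ``p_value = None`` and a message instead of raising.
    """
    mp = [r for r in ratios if r.group == "MP"]
    other = [r for r in ratios if r.group == "non-MP"]
    result: dict = {
        "n_mp": len(mp),
        "n_non_mp": len(other),
        "mean_ratio_mp": float(np.mean([r.ratio for r in mp])) if mp else None,
        "mean_ratio_non_mp": float(np.mean([r.ratio for r in other])) if other else None,
        "pooled_ratio_mp": _pooled_ratio(mp),
        "pooled_ratio_non_mp": _pooled_ratio(other),
        "log_scale": log_scale,
        "p_value": None,
        "message": None,
    }
    if not mp or not other:
        result["message"] = "one group is empty; comparison skipped"
        return result
    a = np.log([r.ratio for r in mp]) if log_scale else np.array([r.ratio for r in mp])
    b = np.log([r.ratio for r in other]) if log_scale else np.array([r.ratio for r in other])
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        result["message"] = "zero variance in both groups; t-test degenerate"
        result["p_value"] = 1.0 if np.mean(a) == np.mean(b) else 0.0
        return result
    t, p = stats.ttest_ind(a, b, equal_var=False)
    result["t_statistic"] = float(t)
    result["p_value"] = float(p)
    return result


def _pooled_ratio(group: Sequence[LocusRatio], pseudocount: float = 0.5) -> Optional[float]:
    if not group:
        return None
    act = sum(r.n_active_pres for r in group)
    rep = sum(r.n_repressed_pres for r in group)
    return (act + pseudocount) / (rep + pseudocount)


def write_states(path, states: Sequence[ChromatinStateCall]) -> None:
    with open(path, "w") as fh:
        fh.write("pre_id\taccessible\tactive\trepressed\tcondition\n")
        for c in states:
            fh.write(
                f"{c.pre_id}\t{int(c.accessible)}\t{int(c.active)}\t"
                f"{int(c.repressed)}\t{c.condition}\n"
            )
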