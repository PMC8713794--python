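"""Differential chromatin state between wild-type and patterning mutants.

The WT pRE catalog is the fixed universe.  For each pRE, each mark
(ATAC, H3K27ac, H3K27me3), and each mutant, the mean reads-per-million
coverage over the pRE interval is computed in both conditions and

    log2fc = log2((mut_rpm + eps) / (wt_rpm + eps)),  eps = 0.25 RPM.

The call is Gain when log2fc >= +tau, Loss when <= -tau (tau default
1.0, boundaries inclusive), otherwise NoChange; pREs whose stronger
condition stays below ``min_rpm`` (default 1 RPM) are always NoChange.
This transparent fold-change rule stands in for a replicate-aware
dispersion model, which the single-library design cannot support.

Per-pRE calls are aggregated to a signed locus direction (+1 for each
activating change: H3K27ac Gain or H3K27me3 Loss; -1 for each
repressing change; ATAC optionally included), compared against
expert-curated RNA-direction annotations, and cross-tabulated against
TF occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .catalog import PutativeRegulatoryElement
from .chromatin import ChromatinStateCall
from .interactome import GeneLocus
from .intervals import CoverageTrack, DEFAULT_TFS, MARK_ASSAYS
from .reporting import percent_int

CALLS = ("Loss", "NoChange", "Gain")
RNA_LEVELS = ("++", "+", "0", "-", "--")


@dataclass(frozen=True)
class DifferentialCall:
    """Per-pRE, per-mark, per-mutant change call with its effect size."""

    pre_id: str
    mark: str
    mutant: str
    log2fc: float
    call: str
    wt_rpm: float
    mut_rpm: float

    def __post_init__(self) -> None:
        if self.mark not in MARK_ASSAYS:
            raise ValueError(f"unknown mark {self.mark!r}")
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        if self.wt_rpm < 0 or self.mut_rpm < 0:
            raise ValueError("RPM values must be non-negative")


@dataclass(frozen=True)
class RnaDirectionRecord:
    """Curated five-level RNA change for one gene in one mutant."""

    gene_id: str
    mutant: str
    level: str

    def __post_init__(self) -> None:
        if self.level not in RNA_LEVELS:
            raise ValueError(
                f"RNA level must be one of {RNA_LEVELS}, got {self.level!r}"
            )

    @property
    def direction(self) -> str:
        if self.level in ("++", "+"):
            return "up"
        if self.level in ("-", "--"):
            return "down"
        return "none"


@dataclass(frozen=True)
class LocusDirection:
    """Signed per-locus summary of differential member pREs."""

    gene_id: str
    mutant: str
    score: int
    n_differential_pres: int

    @property
    def direction(self) -> str:
        if self.score > 0:
            return "activated"
        if self.score < 0:
            return "repressed"
        return "mixed/none"


def call_differential(
    pres: Sequence[PutativeRegulatoryElement],
    wt_track: CoverageTrack,
    mut_track: CoverageTrack,
    mark: str,
    mutant: str,
    tau: float = 1.0,
    min_rpm: float = 1.0,
    eps: float = 0.25,
) -> list[DifferentialCall]:
    """Gain/Loss/NoChange per catalog pRE for one mark and mutant."""
    if mark not in MARK_ASSAYS:
        raise ValueError(f"unknown mark {mark!r}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    calls = []
    for pre in pres:
        wt = wt_track.mean_rpm(pre.interval)
        mut = mut_track.mean_rpm(pre.interval)
        lfc = math.log2((mut + eps) / (wt + eps))
        if max(wt, mut) < min_rpm:
            call = "NoChange"
        elif lfc >= tau:
            call = "Gain"
        elif lfc <= -tau:
            call = "Loss"
        else:
            call = "NoChange"
        calls.append(
            DifferentialCall(
                pre_id=pre.pre_id, mark=mark, mutant=mutant,
                log2fc=lfc, call=call, wt_rpm=wt, mut_rpm=mut,
            )
        )
    return calls


def tally_differential(
    calls: Sequence[DifferentialCall],
    wt_states: Optional[Sequence[ChromatinStateCall]] = None,
    catalog_size: Optional[int] = None,
):
    """Percent Loss / NoChange / Gain per mark for one mutant.

    The primary denominator per mark is the set of *assessed* pREs:
    those carrying that mark's WT peak or receiving a non-NoChange
    call.  When ``catalog_size`` is given, percentages over the whole
    catalog are emitted alongside.  Integer percentages round half-up;
    raw fractions are included.
    """
    import pandas as pd

    mutants = {c.mutant for c in calls}
    if len(mutants) > 1:
        raise ValueError(f"tally one mutant at a time; got {sorted(mutants)}")
    wt_flag = {}
    if wt_states is not None:
        wt_flag = {s.pre_id: s for s in wt_states}
    rows = []
    for mark in MARK_ASSAYS:
        mark_calls = [c for c in calls if c.mark == mark]
        if not mark_calls:
            continue
        assessed = [
            c
            for c in mark_calls
            if c.call != "NoChange"
            or (c.pre_id in wt_flag and wt_flag[c.pre_id].flag(mark))
            or wt_states is None
        ]
        n = len(assessed)
        counts = {k: sum(1 for c in assessed if c.call == k) for k in CALLS}
        row = {
            "mark": mark,
            "n_assessed": n,
            **{f"n_{k.lower()}": counts[k] for k in CALLS},
            **{
                f"pct_{k.lower()}": percent_int(counts[k], n) if n else None
                for k in CALLS
            },
            **{
                f"frac_{k.lower()}": counts[k] / n if n else None
                for k in CALLS
            },
        }
        if catalog_size:
            for k in CALLS:
                n_k = sum(1 for c in mark_calls if c.call == k)
                row[f"pct_{k.lower()}_of_catalog"] = percent_int(n_k, catalog_size)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mark")


#: Sign of each (mark, call) pair for locus-direction scoring.
_ACTIVATING = {("H3K27ac", "Gain"), ("H3K27me3", "Loss")}
_REPRESSING = {("H3K27ac", "Loss"), ("H3K27me3", "Gain")}
_ACTIVATING_ATAC = {("ATAC", "Gain")}
_REPRESSING_ATAC = {("ATAC", "Loss")}


def locus_direction(
    loci: Mapping[str, GeneLocus],
    calls: Sequence[DifferentialCall],
    mutant: str,
    include_atac: bool = False,
) -> list[LocusDirection]:
    """Sum +-1 over differential member pREs to a locus direction.

    +1 per activating change (H3K27ac Gain, H3K27me3 Loss), -1 per
    repressing change (H3K27ac Loss, H3K27me3 Gain).  ATAC Gain/Loss
    contributes only when ``include_atac`` — the locus ratio language
    concerns the histone marks.  Every differential member weighs
    equally; score > 0 is "activated", < 0 "repressed", 0 "mixed/none".
    """
    act = _ACTIVATING | (_ACTIVATING_ATAC if include_atac else set())
    rep = _REPRESSING | (_REPRESSING_ATAC if include_atac else set())
    by_pre: dict[str, list[DifferentialCall]] = {}
    for c in calls:
        if c.mutant != mutant:
            continue
        by_pre.setdefault(c.pre_id, []).append(c)
    out = []
    for gene_id in sorted(loci):
        locus = loci[gene_id]
        score = 0
        diff_pres = 0
        for pre_id in locus.member_pre_ids:
            pre_calls = by_pre.get(pre_id, ())
            contributed = False
            for c in pre_calls:
                if (c.mark, c.call) in act:
                    score += 1
                    contributed = True
                elif (c.mark, c.call) in rep:
                    score -= 1
                    contributed = True
            if contributed:
                diff_pres += 1
        out.append(
            LocusDirection(
                gene_id=gene_id, mutant=mutant, score=score,
                n_differential_pres=diff_pres,
            )
        )
    return out


def concordance(
    locus_directions: Sequence[LocusDirection],
    rna: Sequence[RnaDirectionRecord],
    mutant: str,
) -> dict:
    """Match rate between RNA direction and epigenomic locus direction.

    Only loci with an RNA direction (level != 0) and >= 1 differential
    member pRE are assessed.  A match is (RNA down & repressed) or
    (RNA up & activated).  The rate is an integer percent (half-up);
    ``None`` (NA) when nothing is assessable.
    """
    dirs = {d.gene_id: d for d in locus_directions if d.mutant == mutant}
    assessed = []
    matches = 0
    detail = []
    for rec in rna:
        if rec.mutant != mutant or rec.direction == "none":
            continue
        d = dirs.get(rec.gene_id)
        if d is None or d.n_differential_pres == 0:
            continue
        assessed.append(rec.gene_id)
        match = (rec.direction == "down" and d.direction == "repressed") or (
            rec.direction == "up" and d.direction == "activated"
        )
        matches += match
        detail.append(
            {
                "gene_id": rec.gene_id,
                "rna_direction": rec.direction,
                "locus_direction": d.direction,
                "locus_score": d.score,
                "match": bool(match),
            }
        )
    return {
        "mutant": mutant,
        "n_assessed": len(assessed),
        "n_matches": matches,
        "rate_pct": percent_int(matches, len(assessed)) if assessed else None,
        "detail": detail,
    }


def binding_association(
    calls: Sequence[DifferentialCall],
    pres: Sequence[PutativeRegulatoryElement],
    tf: str,
    mark: str,
    tfs: Sequence[str] = DEFAULT_TFS,
) -> dict:
    """Fraction of each differential class bound by one TF.

    E.g. the fraction of H3K27ac-Loss pREs carrying an LHX2 peak,
    versus the Gain and NoChange classes, plus a 2x2 Fisher exact test
    of Loss-vs-rest against bound-vs-not.  Empty classes give ``None``.
    """
    if tf not in tfs:
        raise ValueError(f"TF {tf!r} not in the configured registry {tuple(tfs)}")
    bound = {p.pre_id: bool(p.occupancy.bound.get(tf, False)) for p in pres}
    classes: dict[str, list[bool]] = {k: [] for k in CALLS}
    for c in calls:
        if c.mark != mark:
            continue
        if c.pre_id not in bound:
            raise ValueError(f"call for unknown pRE {c.pre_id!r}")
        classes[c.call].append(bound[c.pre_id])
    fractions = {
        k: (float(np.mean(v)) if v else None) for k, v in classes.items()
    }
    loss = classes["Loss"]
    rest = classes["Gain"] + classes["NoChange"]
    if loss and rest:
        table = [
            [sum(loss), len(loss) - sum(loss)],
            [sum(rest), len(rest) - sum(rest)],
        ]
        _, p = fisher_exact(table, alternative="two-sided")
    else:
        p = None
    return {
        "tf": tf,
        "mark": mark,
        "fraction_bound": fractions,
        "n": {k: len(v) for k, v in classes.items()},
        "fisher_p_loss_vs_rest": p,
    }


def read_rna_directions(path) -> list[RnaDirectionRecord]:
    """TSV with columns gene_id, mutant, level (one of ++/+/0/-/--)."""
    from .intervals import read_table

    df = read_table(path, dtype=str)
    required = {"gene_id", "mutant", "level"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: RNA table needs columns {sorted(required)}")
    return [
        RnaDirectionRecord(str(r.gene_id), str(r.mutant), str(r.level))
        for r in df.itertuples(index=False)
    ]


def write_calls(path, calls: Sequence[DifferentialCall]) -> None:
    with open(path, "w") as fh:
        fh.write("pre_id\tmark\tmutant\twt_rpm\tmut_rpm\tlog2fc\tcall\n")
        for c in calls:
            fh.write(
                f"{c.pre_id}\t{c.mark}\t{c.mutant}\t{c.wt_rpm:.4f}\t"
                f"{c.mut_rpm:.4f}\t{c.log2fc:.4f}\t{c.call}\n"
            )
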