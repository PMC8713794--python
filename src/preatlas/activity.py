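"""Enhancer-assay activity vs combinatorial TF binding.

Transgenic-assay enhancers (VISTA-style) carry a categorical activity
class — Pallial, Subpallial, Nontelencephalic, or Inactive — and, for
pallial elements, regional labels (LVP, DP, MP) and activity-gradient
labels (RC, CR, DV, VD).  This module annotates each element with the
set of profiled TFs whose WT peaks overlap it, summarizes binding-class
composition per activity class, classifies peak-height quartiles, and
computes the binding<->activity correlalogram: for every TF x label
pair, the phi coefficient of the two binary vectors with a two-sided
Fisher exact test, calling association at p < alpha (default 0.01,
uncorrected — a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .catalog import OccupancyVector
from .intervals import DEFAULT_TFS, GenomicInterval, IntervalIndex, PeakCall

ACTIVITY_CLASSES = ("Pallial", "Subpallial", "Nontelencephalic", "Inactive")
REGION_LABELS = ("LVP", "DP", "MP")
GRADIENT_LABELS = ("RC", "CR", "DV", "VD")

#: Default binding-class bins for composition heatmaps: unbound, 1-3, 4-5.
DEFAULT_BINS = ((0,), (1, 2, 3), (4, 5))


@dataclass(frozen=True)
class EnhancerAssayRecord:
    """One in vivo tested enhancer with its curated activity labels."""

    element_id: str
    interval: GenomicInterval
    activity_class: str
    region_labels: frozenset = frozenset()
    gradient_labels: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "region_labels", frozenset(self.region_labels))
        object.__setattr__(self, "gradient_labels", frozenset(self.gradient_labels))
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ValueError(
                f"{self.element_id}: unknown activity class "
                f"{self.activity_class!r}"
            )
        bad = self.region_labels - set(REGION_LABELS)
        if bad:
            raise ValueError(f"{self.element_id}: unknown region labels {sorted(bad)}")
        bad = self.gradient_labels - set(GRADIENT_LABELS)
        if bad:
            raise ValueError(f"{self.element_id}: unknown gradient labels {sorted(bad)}")
        if self.activity_class != "Pallial" and (
            self.region_labels or self.gradient_labels
        ):
            raise ValueError(
                f"{self.element_id}: region/gradient labels only apply to "
                f"Pallial elements"
            )


@dataclass(frozen=True)
class AssociationResult:
    """One TF x label cell of the correlalogram."""

    tf: str
    label: str
    phi: float
    p_value: float
    significant: bool
    direction: str  # correlated | anticorrelated | none
    degenerate: bool = False


def annotate_enhancer_binding(
    enhancers: Sequence[EnhancerAssayRecord],
    tf_peaks: Mapping[str, Sequence[PeakCall]],
) -> dict[str, OccupancyVector]:
    """Per-element bound-TF set, by >= 1 bp overlap with any WT peak.

    Two peaks of the same TF over one element count once (set
    semantics); elements overlapping nothing get count 0.
    """
    ids = [e.element_id for e in enhancers]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate element ids: {dupes}")
    indexes = {
        tf: IntervalIndex((p.interval, p) for p in peaks)
        for tf, peaks in tf_peaks.items()
    }
    out = {}
    for e in enhancers:
        bound = {
            tf: bool(idx.overlapping(e.interval)) for tf, idx in indexes.items()
        }
        out[e.element_id] = OccupancyVector(bound)
    return out


def class_composition(
    enhancers: Sequence[EnhancerAssayRecord],
    occupancy: Mapping[str, OccupancyVector],
    bins: Sequence[Sequence[int]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Percent of each activity class falling in each binding-class bin.

    Rows (activity classes) sum to 100 within rounding; classes with no
    elements are omitted.  Percentages are floats; round for display.
    """
    import warnings

    labels = ["-".join(map(str, (b[0], b[-1]))) if len(b) > 1 else str(b[0]) for b in bins]
    rows = {}
    for cls in ACTIVITY_CLASSES:
        counts = [
            sum(
                1
                for e in enhancers
                if e.activity_class == cls and occupancy[e.element_id].count in b
            )
            for b in bins
        ]
        total = sum(counts)
        if total == 0:
            warnings.warn(f"activity class {cls!r} has no elements; row omitted")
            continue
        rows[cls] = [c / total * 100.0 for c in counts]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def quartile_profile(
    enhancers: Sequence[EnhancerAssayRecord],
    ranked_tf_peaks: Mapping[str, Sequence[PeakCall]],
    threshold: float = 25.0,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Classify each element x TF cell by normalized peak height.

    ``ranked_tf_peaks`` must carry percentile-rank signals (see
    ``catalog.normalize_signal``).  Cells are ``no_peak`` when unbound,
    ``small`` when the aggregated rank is <= ``threshold`` (<=25th
    percentile by default), else ``robust``.  Aggregation over multiple
    overlapping peaks is ``max`` by default (``mean`` available).
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    indexes = {
        tf: IntervalIndex((p.interval, p) for p in peaks)
        for tf, peaks in ranked_tf_peaks.items()
    }
    data = {}
    for e in enhancers:
        row = {}
        for tf, idx in indexes.items():
            hits = [p.signal for _, p in idx.overlapping(e.interval)]
            if not hits:
                row[tf] = "no_peak"
            else:
                agg = max(hits) if aggregate == "max" else float(np.mean(hits))
                row[tf] = "small" if agg <= threshold else "robust"
        data[e.element_id] = row
    return pd.DataFrame.from_dict(data, orient="index")


def phi_coefficient(table: np.ndarray) -> float:
    """Phi for a 2x2 table; equals the Pearson r of the binary vectors."""
    table = np.asarray(table, dtype=float)
    (a, b), (c, d) = table
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return float((a * d - b * c) / np.sqrt(denom))


def _label_vectors(
    enhancers: Sequence[EnhancerAssayRecord],
    labels: Optional[Sequence[str]],
) -> dict[str, np.ndarray]:
    wanted = labels or list(ACTIVITY_CLASSES) + list(REGION_LABELS) + list(GRADIENT_LABELS)
    vecs = {}
    for label in wanted:
        if label in ACTIVITY_CLASSES:
            v = [e.activity_class == label for e in enhancers]
        elif label in REGION_LABELS:
            v = [label in e.region_labels for e in enhancers]
        elif label in GRADIENT_LABELS:
            v = [label in e.gradient_labels for e in enhancers]
        else:
            raise ValueError(f"unknown label {label!r}")
        vecs[label] = np.array(v, dtype=bool)
    return vecs


def correlalogram(
    enhancers: Sequence[EnhancerAssayRecord],
    occupancy: Mapping[str, OccupancyVector],
    alpha: float = 0.01,
    labels: Optional[Sequence[str]] = None,
    tfs: Sequence[str] = DEFAULT_TFS,
    bh_correct: bool = False,
) -> list[AssociationResult]:
    """Binding <-> activity association for every TF x label pair.

    For each pair, the 2x2 contingency of (bound by TF) x (carries
    label) gives a phi coefficient and a two-sided Fisher exact p.
    Significance is an uncorrected p < alpha gate by default;
    ``bh_correct`` applies Benjamini-Hochberg across all pairs instead.
    Degenerate margins (a label all-positive or all-negative) yield
    direction "none" with ``degenerate=True`` rather than an error.
    """
    vecs = _label_vectors(enhancers, labels)
    bound = {
        tf: np.array([occupancy[e.element_id][tf] for e in enhancers], dtype=bool)
        for tf in tfs
    }
    raw = []
    for tf in tfs:
        bv = bound[tf]
        for label, lv in vecs.items():
            table = np.array(
                [
                    [np.sum(bv & lv), np.sum(bv & ~lv)],
                    [np.sum(~bv & lv), np.sum(~bv & ~lv)],
                ]
            )
            degenerate = lv.all() or (~lv).all() or bv.all() or (~bv).all()
            phi = phi_coefficient(table)
            if degenerate or np.isnan(phi):
                raw.append((tf, label, 0.0 if np.isnan(phi) else phi, 1.0, True))
            else:
                _, p = fisher_exact(table, alternative="two-sided")
                raw.append((tf, label, phi, float(p), False))

    pvals = np.array([r[3] for r in raw])
    if bh_correct:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in list(enumerate(order, 1))[::-1]:
            prev = min(prev, pvals[idx] * m / rank)
            adj[idx] = prev
        pvals = adj

    results = []
    for (tf, label, phi, _, degenerate), p in zip(raw, pvals):
        significant = (not degenerate) and p < alpha
        if degenerate or not significant:
            direction = "none"
        else:
            direction = "correlated" if phi > 0 else "anticorrelated"
        results.append(
            AssociationResult(
                tf=tf, label=label, phi=phi, p_value=float(p),
                significant=significant, direction=direction,
                degenerate=degenerate,
            )
        )
    return results


def logistic_correlalogram(
    enhancers: Sequence[EnhancerAssayRecord],
    occupancy: Mapping[str, OccupancyVector],
    labels: Optional[Sequence[str]] = None,
    tfs: Sequence[str] = DEFAULT_TFS,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Joint logistic model per label: label ~ the five TF indicators.

    An alternative reading of "combinations of TF binding": each label
    is regressed on all TF indicators at once, so coefficients are
    adjusted for co-binding.  Returns per (label, tf) the coefficient,
    Wald p, and direction at the same alpha gate.
    """
    from scipy.optimize import minimize

    vecs = _label_vectors(enhancers, labels)
    X = np.column_stack(
        [np.ones(len(enhancers))]
        + [
            np.array([occupancy[e.element_id][tf] for e in enhancers], dtype=float)
            for tf in tfs
        ]
    )
    rows = []
    for label, y in vecs.items():
        y = y.astype(float)
        if y.all() or not y.any():
            for tf in tfs:
                rows.append((label, tf, np.nan, 1.0, "none"))
            continue

        def nll(beta):
            z = X @ beta
            return float(np.sum(np.logaddexp(0, z) - y * z)) + 1e-4 * beta @ beta

        res = minimize(nll, np.zeros(X.shape[1]), method="BFGS")
        beta = res.x
        p_hat = 1 / (1 + np.exp(-(X @ beta)))
        W = p_hat * (1 - p_hat)
        try:
            cov = np.linalg.inv((X * W[:, None]).T @ X + 2e-4 * np.eye(X.shape[1]))
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(X.shape[1], np.nan)
        from scipy.stats import norm

        for j, tf in enumerate(tfs, start=1):
            z = beta[j] / se[j] if se[j] > 0 else 0.0
            p = 2 * norm.sf(abs(z))
            direction = (
                ("correlated" if beta[j] > 0 else "anticorrelated")
                if p < alpha
                else "none"
            )
            rows.append((label, tf, beta[j], float(p), direction))
    return pd.DataFrame(rows, columns=["label", "tf", "coef", "p_value", "direction"])


def read_enhancer_table(bed_path, labels_path) -> list[EnhancerAssayRecord]:
    """Read enhancers from BED6 plus a TSV sidecar of labels.

    Sidecar columns: element_id, activity_class, region_labels,
    gradient_labels (comma-separated sets, '.' for empty).
    """
    from .intervals import read_bed, read_table

    beds = {r.name: r.interval for r in read_bed(bed_path)}
    df = read_table(labels_path, dtype=str).fillna(".")
    records = []
    for row in df.itertuples(index=False):
        eid = str(row.element_id)
        if eid not in beds:
            raise ValueError(f"label table names unknown element {eid!r}")
        parse = lambda s: frozenset() if s in (".", "") else frozenset(s.split(","))
        records.append(
            EnhancerAssayRecord(
                element_id=eid,
                interval=beds[eid],
                activity_class=str(row.activity_class),
                region_labels=parse(str(row.region_labels)),
                gradient_labels=parse(str(row.gradient_labels)),
            )
        )
    return records


def write_correlalogram(path, results: Sequence[AssociationResult]) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tlabel\tphi\tp_value\tsignificant\tdirection\n")
        for r in results:
            fh.write(
                f"{r.tf}\t{r.label}\t{r.phi:.4f}\t{r.p_value:.4g}\t"
                f"{int(r.significant)}\t{r.direction}\n"
            )
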