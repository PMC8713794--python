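"""Synthetic multi-assay dataset generator with planted structure.

Generates every input the pipeline consumes — gene models, per-TF WT
ChIP-seq peaks, mark peaks, bedGraph coverage for WT and mutants,
loop bin pairs, an enhancer-assay table, and RNA-direction labels —
with the statistical structure the analyses are designed to detect:

* **Co-binding.** Each binding site carries a latent strength
  ``u ~ Uniform(0,1)``; TF t binds with probability
  ``sigmoid(a + b (u - 1/2))`` where ``b = 6 * cobinding_strength``.
  Shared ``u`` induces combinatorial occupancy; ``cobinding_strength=0``
  reduces to independent Binomial(5, sigmoid(a)) occupancy.
* **Occupancy-coupled marks.** P(ATAC | k) and P(H3K27ac | k) increase
  linearly in the occupancy count k while P(H3K27me3 | k) decreases
  (defaults anchored to the reported progenitor-chromatin profile:
  ATAC 0.25 + 0.15 k, H3K27ac 0.15 + 0.125 k, H3K27me3 0.60 - 0.10 k).
* **Activity labels.** Enhancer elements draw activity classes and
  pallial region/gradient labels from logistic models in k with
  positive LVP/RC and negative MP/DV couplings.
* **Loops.** A configured fraction of bound sites loop to the nearest
  gene's TSS bin at 5-kb resolution, FDR below 0.01; decoy and
  above-threshold pairs are added to exercise filtering.
* **Mutant effects.** A planted fraction of catalog sites gets a
  mark-specific coverage fold change of +-|log2FC| in each mutant;
  coverage is per-site Poisson (flat within the interval) over a low
  uniform background.  Mutant libraries are twice the WT size so
  RPM normalization is genuinely exercised.
* **RNA directions.** Each network gene's label derives from the signed
  sum of its planted member-site histone changes, with optional label
  noise.

All randomness flows from ``SimulationConfig.seed``; two runs with the
same config are byte-identical on disk.  Truth tables record every
planted assignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    CONDITIONS,
    DEFAULT_TFS,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    MARK_ASSAYS,
    PeakCall,
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_gene_table,
    BedRecord,
)
from .interactome import BinPairInteraction
from .activity import EnhancerAssayRecord
from .differential import RnaDirectionRecord


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """All knobs of the generator; every probability clamps to [0,1]."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 60_000_000
    n_genes: int = 300
    n_network_genes: int = 38
    n_mp_genes: int = 6
    n_sites: int = 240
    n_enhancer_sites: int = 500
    tf_names: tuple = DEFAULT_TFS
    # binding model
    cobinding_strength: float = 0.8
    bind_intercept: float = -0.2
    bind_slope_scale: float = 6.0
    # geometry
    site_grid: int = 5000
    peak_halfwidth: tuple = (150, 400)
    peak_jitter_sd: float = 60.0
    mark_halfwidth: int = 400
    enhancer_halfwidth: int = 600
    enhancer_unbound_frac: float = 0.10
    # marks: mark -> (base rate, per-occupancy slope)
    mark_probs: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "ATAC": (0.25, 0.15),
            "H3K27ac": (0.15, 0.125),
            "H3K27me3": (0.60, -0.10),
        }
    )
    # medial-pallium planting: member sites of MP loci are repressed
    mp_ac_prob: float = 0.15
    mp_me3_prob: float = 0.80
    # activity-label logistic coefficients on occupancy count
    activity_coefs: Mapping[str, tuple] = field(
        default_factory=lambda: {
            "Pallial": (-0.4, 0.25),
            "LVP": (-2.6, 1.0),
            "MP": (1.8, -1.3),
            "DP": (0.0, 0.0),
            "RC": (-2.6, 1.0),
            "DV": (1.6, -1.2),
            "CR": (-0.85, 0.0),
            "VD": (-1.1, 0.0),
        }
    )
    # loops
    loop_rate: float = 0.5
    resolution: int = 5000
    n_decoy_loops: int = 20
    n_unfiltered_loops: int = 10
    # coverage / differential
    peak_rpm: float = 20.0
    background_rpm: float = 0.05
    wt_library_size: float = 1e6
    mut_library_factor: float = 2.0
    mutants: tuple = ("Emx2-KO", "Nr2f1-KO", "Pax6-KO")
    mutant_frac: float = 0.10
    mutant_lfc: float = 2.0
    mutant_gain_frac: float = 0.3
    # RNA labels
    rna_label_noise: float = 0.1
    window_bp: int = 100_000
    # planted network enrichment: fraction of network genes drawn from the
    # satisfying pool (None = uniform draw, i.e. no planted enrichment)
    network_satisfying_frac: Optional[float] = 0.79

    def __post_init__(self) -> None:
        n_slots = self.n_chroms * (self.chrom_length // self.site_grid - 2)
        if self.n_sites + self.n_enhancer_sites > n_slots:
            raise ValueError(
                f"chromosomes too short: {self.n_sites + self.n_enhancer_sites} "
                f"sites requested but only {n_slots} grid slots available"
            )
        if not 0 <= self.mutant_gain_frac <= 1:
            raise ValueError("mutant_gain_frac must be in [0,1]")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticDataset:
    """In-memory view of one simulated study, plus its truth tables."""

    config: SimulationConfig
    genes: list
    network_genes: list
    mp_genes: list
    tf_peaks: dict
    tf_library_sizes: dict
    mark_peaks: dict  # WT mark peak calls
    tracks: dict  # (mark, condition) -> CoverageTrack
    loops: list
    raw_loop_rows: list  # pre-filter BEDPE rows incl. above-threshold FDRs
    enhancers: list
    rna: list
    truth_sites: pd.DataFrame
    truth_differential: pd.DataFrame
    truth_membership: pd.DataFrame
    out_dir: Optional[Path] = None


# ---------------------------------------------------------------------------

def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    gid = 0
    for ci, chrom in enumerate(cfg.chromosomes):
        n = int(per_chrom[ci])
        slot = cfg.chrom_length // (n + 1)
        for j in range(n):
            gid += 1
            body_len = int(rng.integers(5_000, 40_000))
            center = (j + 1) * slot + int(rng.integers(-slot // 4, slot // 4))
            start = max(0, center - body_len // 2)
            end = start + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    interval=GenomicInterval(chrom, start, end, strand),
                    tss=tss,
                    strand=strand,
                )
            )
    return genes


def _place_sites(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Site centers on a spaced grid so neighbouring peaks never merge."""
    n_total = cfg.n_sites + cfg.n_enhancer_sites
    per_chrom = np.full(cfg.n_chroms, n_total // cfg.n_chroms)
    per_chrom[: n_total % cfg.n_chroms] += 1
    rows = []
    for ci, chrom in enumerate(cfg.chromosomes):
        grid = np.arange(1, cfg.chrom_length // cfg.site_grid - 1) * cfg.site_grid
        picks = np.sort(rng.choice(grid, size=int(per_chrom[ci]), replace=False))
        offsets = rng.integers(1000, cfg.site_grid - 1000, size=len(picks))
        for center in picks + offsets:
            rows.append({"chrom": chrom, "center": int(center)})
    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df["site_id"] = [f"site{i + 1:04d}" for i in range(len(df))]
    df["kind"] = ["locus"] * cfg.n_sites + ["assay"] * cfg.n_enhancer_sites
    df["u"] = rng.random(len(df))
    return df


def _draw_binding(
    cfg: SimulationConfig, rng: np.random.Generator, sites: pd.DataFrame
) -> pd.DataFrame:
    b = cfg.bind_slope_scale * cfg.cobinding_strength
    p = _sigmoid(cfg.bind_intercept + b * (sites["u"].to_numpy() - 0.5))
    forced_unbound = np.zeros(len(sites), dtype=bool)
    assay = (sites["kind"] == "assay").to_numpy()
    n_forced = int(round(cfg.enhancer_unbound_frac * assay.sum()))
    if n_forced:
        idx = rng.choice(np.flatnonzero(assay), size=n_forced, replace=False)
        forced_unbound[idx] = True
    for tf in cfg.tf_names:
        draw = rng.random(len(sites)) < p
        sites[f"bound_{tf}"] = draw & ~forced_unbound
    sites["k"] = sum(sites[f"bound_{tf}"].astype(int) for tf in cfg.tf_names)
    sites["forced_unbound"] = forced_unbound
    return sites


def _make_tf_peaks(
    cfg: SimulationConfig, rng: np.random.Generator, sites: pd.DataFrame
) -> tuple[dict, dict]:
    # per-TF depth factors give unequal library sizes; RPM + ranks undo them
    depth_factor = {
        tf: 0.5 + 1.5 * i for i, tf in enumerate(cfg.tf_names, start=1)
    }
    tf_peaks: dict[str, list[PeakCall]] = {tf: [] for tf in cfg.tf_names}
    lo, hi = cfg.peak_halfwidth
    for row in sites.itertuples(index=False):
        for tf in cfg.tf_names:
            if not getattr(row, f"bound_{tf}"):
                continue
            center = row.center + int(round(rng.normal(0, cfg.peak_jitter_sd)))
            half = int(rng.integers(lo, hi + 1))
            signal = depth_factor[tf] * (0.5 + row.u) * float(
                np.exp(rng.normal(0, 0.4))
            )
            tf_peaks[tf].append(
                PeakCall(
                    interval=GenomicInterval(row.chrom, max(0, center - half), center + half),
                    assay=tf,
                    condition="WT",
                    signal=signal,
                    name=f"{tf}_{row.site_id}",
                )
            )
    library_sizes = {tf: depth_factor[tf] * 1e6 for tf in cfg.tf_names}
    return tf_peaks, library_sizes


def _pick_network(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: Sequence[GeneModel],
    sites: pd.DataFrame,
) -> tuple[list[str], np.ndarray]:
    """Choose network genes, optionally enriched for satisfying loci."""
    from .intervals import distance_to_tss

    centers = {c: g.sort_values("center") for c, g in sites.groupby("chrom")}
    satisfies = np.zeros(len(genes), dtype=bool)
    for gi, gene in enumerate(genes):
        sub = centers.get(gene.chrom)
        if sub is None:
            continue
        c = sub["center"].to_numpy()
        k = sub["k"].to_numpy()
        d = np.abs(c - gene.tss)
        satisfies[gi] = bool(np.any((k >= 3) & (d >= 2500 + 600) & (d <= cfg.window_bp - 600)))
    ids = np.array([g.gene_id for g in genes])
    if cfg.network_satisfying_frac is None:
        chosen = rng.choice(ids, size=cfg.n_network_genes, replace=False)
    else:
        n_sat = int(round(cfg.network_satisfying_frac * cfg.n_network_genes))
        sat_pool = ids[satisfies]
        other_pool = ids[~satisfies]
        n_sat = min(n_sat, len(sat_pool))
        n_other = cfg.n_network_genes - n_sat
        if n_other > len(other_pool):
            raise ValueError("not enough non-satisfying genes for the network draw")
        chosen = np.concatenate(
            [
                rng.choice(sat_pool, size=n_sat, replace=False),
                rng.choice(other_pool, size=n_other, replace=False),
            ]
        )
    chosen = sorted(str(g) for g in chosen)
    return chosen, satisfies


def _truth_membership(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    sites: pd.DataFrame,
    loops_by_gene: Mapping[str, list[str]],
) -> pd.DataFrame:
    """Planted locus membership mirroring the assignment rule:
    sites within the loop-extended +-100 kb window, plus looped sites."""
    by_id = {g.gene_id: g for g in genes}
    site_pos = sites.set_index("site_id")[["chrom", "center"]]
    rows = []
    for gene in genes:
        win_lo = max(0, gene.interval.start - cfg.window_bp)
        win_hi = gene.interval.end + cfg.window_bp
        looped = loops_by_gene.get(gene.gene_id, [])
        for sid in looped:
            pos = site_pos.loc[sid]
            if pos["chrom"] == gene.chrom:
                win_lo = min(win_lo, int(pos["center"]) - cfg.resolution)
                win_hi = max(win_hi, int(pos["center"]) + cfg.resolution)
        sub = sites[(sites["chrom"] == gene.chrom)]
        in_win = sub[(sub["center"] >= win_lo) & (sub["center"] <= win_hi)]
        member = set(in_win["site_id"]) | set(looped)
        for sid in sorted(member):
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "site_id": sid,
                    "looped": sid in set(looped),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "site_id", "looped"])


def _clamp01(x):
    return float(min(1.0, max(0.0, x)))


def simulate(
    config: SimulationConfig, out_dir: Optional[str] = None
) -> SyntheticDataset:
    """Generate a full synthetic study; optionally write it to disk."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes = _place_genes(cfg, rng)
    sites = _place_sites(cfg, rng)
    sites = _draw_binding(cfg, rng, sites)
    tf_peaks, tf_library_sizes = _make_tf_peaks(cfg, rng, sites)
    network_genes, satisfies_truth = _pick_network(cfg, rng, genes, sites)
    mp_genes = sorted(
        str(g)
        for g in rng.choice(network_genes, size=min(cfg.n_mp_genes, len(network_genes)), replace=False)
    )

    # ---- loops: bound locus sites to the nearest gene TSS bin ----------
    by_chrom_tss = {
        chrom: sorted(
            (g.tss, g.gene_id) for g in genes if g.chrom == chrom
        )
        for chrom in cfg.chromosomes
    }
    res = cfg.resolution
    loop_rows = []  # (a1, a2, fdr) raw BEDPE rows
    loops_by_gene: dict[str, list[str]] = {}
    pre_sites = sites[(sites["kind"] == "locus") & (sites["k"] >= 1)]
    for row in pre_sites.itertuples(index=False):
        if rng.random() >= cfg.loop_rate:
            continue
        tsses = by_chrom_tss[row.chrom]
        if not tsses:
            continue
        pos = np.array([t for t, _ in tsses])
        gi = int(np.argmin(np.abs(pos - row.center)))
        tss, gene_id = tsses[gi]
        pbin = tss // res
        sbin = row.center // res
        if pbin == sbin:
            continue
        a1 = GenomicInterval(row.chrom, pbin * res, (pbin + 1) * res)
        a2 = GenomicInterval(row.chrom, sbin * res, (sbin + 1) * res)
        fdr = float(rng.uniform(1e-4, 0.009))
        loop_rows.append((a1, a2, fdr))
        loops_by_gene.setdefault(gene_id, []).append(row.site_id)
    # decoys between random non-promoter bins, and above-threshold rows
    n_bins = cfg.chrom_length // res
    for _ in range(cfg.n_decoy_loops):
        chrom = cfg.chromosomes[int(rng.integers(cfg.n_chroms))]
        b1, b2 = rng.integers(1, n_bins - 1, size=2)
        if b1 == b2:
            continue
        loop_rows.append(
            (
                GenomicInterval(chrom, int(b1) * res, (int(b1) + 1) * res),
                GenomicInterval(chrom, int(b2) * res, (int(b2) + 1) * res),
                float(rng.uniform(1e-4, 0.009)),
            )
        )
    for _ in range(cfg.n_unfiltered_loops):
        chrom = cfg.chromosomes[int(rng.integers(cfg.n_chroms))]
        b1, b2 = rng.integers(1, n_bins - 1, size=2)
        if b1 == b2:
            continue
        loop_rows.append(
            (
                GenomicInterval(chrom, int(b1) * res, (int(b1) + 1) * res),
                GenomicInterval(chrom, int(b2) * res, (int(b2) + 1) * res),
                float(rng.uniform(0.02, 0.5)),
            )
        )
    loops = [
        BinPairInteraction(a1, a2, resolution=res, fdr=fdr)
        for a1, a2, fdr in loop_rows
        if fdr < 0.01
    ]

    membership = _truth_membership(cfg, genes, sites, loops_by_gene)
    mp_member_sites = set(
        membership[membership["gene_id"].isin(mp_genes)]["site_id"]
    )

    # ---- WT mark flags -------------------------------------------------
    for mark in MARK_ASSAYS:
        base, slope = cfg.mark_probs[mark]
        probs = np.array([_clamp01(base + slope * k) for k in sites["k"]])
        flags = rng.random(len(sites)) < probs
        sites[f"mark_{mark}"] = flags
    # medial-pallium planting: repress member sites of MP gene loci
    if mp_member_sites:
        is_mp = sites["site_id"].isin(mp_member_sites).to_numpy()
        sites.loc[is_mp, "mark_H3K27ac"] = rng.random(is_mp.sum()) < cfg.mp_ac_prob
        sites.loc[is_mp, "mark_H3K27me3"] = rng.random(is_mp.sum()) < cfg.mp_me3_prob

    mark_peaks: dict[str, list[PeakCall]] = {m: [] for m in MARK_ASSAYS}
    hw = cfg.mark_halfwidth
    for row in sites.itertuples(index=False):
        for mark in MARK_ASSAYS:
            if getattr(row, f"mark_{mark}"):
                mark_peaks[mark].append(
                    PeakCall(
                        interval=GenomicInterval(
                            row.chrom, max(0, row.center - hw), row.center + hw
                        ),
                        assay=mark,
                        condition="WT",
                        signal=cfg.peak_rpm,
                        name=f"{mark}_{row.site_id}",
                    )
                )

    # ---- planted mutant effects ---------------------------------------
    diff_rows = []
    catalog_sites = sites[sites["k"] >= 1]
    for mutant in cfg.mutants:
        eligible = catalog_sites[
            catalog_sites[[f"mark_{m}" for m in MARK_ASSAYS]].any(axis=1)
        ]
        n_perturb = int(round(cfg.mutant_frac * len(catalog_sites)))
        n_perturb = min(n_perturb, len(eligible))
        if n_perturb == 0:
            continue
        chosen = rng.choice(eligible.index.to_numpy(), size=n_perturb, replace=False)
        for idx in chosen:
            row = sites.loc[idx]
            present = [m for m in MARK_ASSAYS if row[f"mark_{m}"]]
            mark = present[int(rng.integers(len(present)))]
            direction = "Gain" if rng.random() < cfg.mutant_gain_frac else "Loss"
            diff_rows.append(
                {
                    "mutant": mutant,
                    "site_id": row["site_id"],
                    "mark": mark,
                    "direction": direction,
                    "log2fc": cfg.mutant_lfc if direction == "Gain" else -cfg.mutant_lfc,
                }
            )
    truth_differential = pd.DataFrame(
        diff_rows, columns=["mutant", "site_id", "mark", "direction", "log2fc"]
    )

    # ---- coverage tracks ----------------------------------------------
    tracks: dict[tuple, CoverageTrack] = {}
    planted = {
        (r["mutant"], r["site_id"], r["mark"]): r["log2fc"]
        for _, r in truth_differential.iterrows()
    }
    for mark in MARK_ASSAYS:
        for condition in ("WT",) + tuple(cfg.mutants):
            lib = cfg.wt_library_size * (
                1.0 if condition == "WT" else cfg.mut_library_factor
            )
            depth_scale = lib / 1e6  # depth units per RPM
            steps = []
            flagged = sites[sites[f"mark_{mark}"]].sort_values(["chrom", "center"])
            site_steps: dict[str, list] = {c: [] for c in cfg.chromosomes}
            for row in flagged.itertuples(index=False):
                target = cfg.peak_rpm
                if condition != "WT":
                    lfc = planted.get((condition, row.site_id, mark))
                    if lfc is not None:
                        target = cfg.peak_rpm * 2.0 ** lfc
                start = max(0, row.center - hw)
                end = row.center + hw
                width = end - start
                depth = (
                    rng.poisson(target * width) / width + cfg.background_rpm
                ) * depth_scale
                site_steps[row.chrom].append((start, end, depth))
            bg = cfg.background_rpm * depth_scale
            for chrom in cfg.chromosomes:
                cursor = 0
                for start, end, depth in sorted(site_steps[chrom]):
                    if start > cursor:
                        steps.append(
                            (GenomicInterval(chrom, cursor, start), bg)
                        )
                    steps.append((GenomicInterval(chrom, start, end), depth))
                    cursor = end
                if cursor < cfg.chrom_length:
                    steps.append(
                        (GenomicInterval(chrom, cursor, cfg.chrom_length), bg)
                    )
            tracks[(mark, condition)] = CoverageTrack(steps, library_size=lib)

    # ---- enhancer assay table ------------------------------------------
    coefs = cfg.activity_coefs
    enhancers = []
    assay_sites = sites[sites["kind"] == "assay"]
    ehw = cfg.enhancer_halfwidth
    for i, row in enumerate(assay_sites.itertuples(index=False), start=1):
        k = int(row.k)
        p_pall = _clamp01(_sigmoid(coefs["Pallial"][0] + coefs["Pallial"][1] * k))
        if rng.random() < p_pall:
            cls = "Pallial"
        else:
            w_sub = 1.0 + 0.15 * k
            w_non = 1.0
            w_ina = max(0.2, 1.6 - 0.2 * k)
            w = np.array([w_sub, w_non, w_ina])
            cls = ("Subpallial", "Nontelencephalic", "Inactive")[
                int(rng.choice(3, p=w / w.sum()))
            ]
        region, gradient = set(), set()
        if cls == "Pallial":
            for label, bucket in (
                ("LVP", region), ("MP", region), ("DP", region),
                ("RC", gradient), ("CR", gradient),
                ("DV", gradient), ("VD", gradient),
            ):
                a, bcoef = coefs[label]
                if rng.random() < _sigmoid(a + bcoef * k):
                    bucket.add(label)
        enhancers.append(
            EnhancerAssayRecord(
                element_id=f"el{i:04d}",
                interval=GenomicInterval(
                    row.chrom, max(0, row.center - ehw), row.center + ehw
                ),
                activity_class=cls,
                region_labels=frozenset(region),
                gradient_labels=frozenset(gradient),
            )
        )

    # ---- RNA direction labels ------------------------------------------
    rna = []
    member_by_gene = {
        g: set(sub["site_id"]) for g, sub in membership.groupby("gene_id")
    }
    sign = {
        ("H3K27ac", "Gain"): 1, ("H3K27me3", "Loss"): 1,
        ("H3K27ac", "Loss"): -1, ("H3K27me3", "Gain"): -1,
    }
    for gene_id in network_genes:
        members = member_by_gene.get(gene_id, set())
        for mutant in cfg.mutants:
            sub = truth_differential[
                (truth_differential["mutant"] == mutant)
                & (truth_differential["site_id"].isin(members))
            ]
            score = sum(
                sign.get((r["mark"], r["direction"]), 0) for _, r in sub.iterrows()
            )
            if score >= 2:
                level = "++"
            elif score == 1:
                level = "+"
            elif score <= -2:
                level = "--"
            elif score == -1:
                level = "-"
            else:
                level = "0"
            if cfg.rna_label_noise > 0 and rng.random() < cfg.rna_label_noise:
                others = [l for l in ("++", "+", "0", "-", "--") if l != level]
                level = others[int(rng.integers(len(others)))]
            rna.append(RnaDirectionRecord(gene_id=gene_id, mutant=mutant, level=level))

    truth_sites = sites.copy()
    truth_sites["in_mp_locus"] = truth_sites["site_id"].isin(mp_member_sites)

    dataset = SyntheticDataset(
        config=cfg,
        genes=genes,
        network_genes=network_genes,
        mp_genes=mp_genes,
        tf_peaks=tf_peaks,
        tf_library_sizes=tf_library_sizes,
        mark_peaks=mark_peaks,
        tracks=tracks,
        loops=loops,
        raw_loop_rows=loop_rows,
        enhancers=enhancers,
        rna=rna,
        truth_sites=truth_sites,
        truth_differential=truth_differential,
        truth_membership=membership,
    )
    if out_dir is not None:
        dataset.out_dir = write_dataset(dataset, out_dir)
    return dataset


# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir) -> Path:
    """Write every pipeline input plus truth/*.tsv under ``out_dir``."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    write_gene_table(out / "genes.tsv", ds.genes)
    for tf, peaks in ds.tf_peaks.items():
        write_bed(
            out / "peaks" / f"{tf}.bed",
            [BedRecord(p.interval, p.name or ".", p.signal) for p in peaks],
        )
    for mark, peaks in ds.mark_peaks.items():
        write_bed(
            out / "peaks" / f"{mark}_WT.bed",
            [BedRecord(p.interval, p.name or ".", p.signal) for p in peaks],
        )
    lib_index = {"tf": ds.tf_library_sizes, "tracks": {}}
    for (mark, condition), track in ds.tracks.items():
        name = f"{mark}_{condition}"
        write_bedgraph(out / "coverage" / f"{name}.bedGraph", track)
        lib_index["tracks"][name] = track.library_size
    with open(out / "library_sizes.json", "w") as fh:
        json.dump(lib_index, fh, indent=1, sort_keys=True)
    write_bedpe(out / f"loops_{ds.config.resolution // 1000}kb.bedpe", ds.raw_loop_rows)

    write_bed(
        out / "enhancers.bed",
        [BedRecord(e.interval, e.element_id) for e in ds.enhancers],
    )
    with open(out / "enhancer_labels.tsv", "w") as fh:
        fh.write("element_id\tactivity_class\tregion_labels\tgradient_labels\n")
        for e in ds.enhancers:
            r = ",".join(sorted(e.region_labels)) or "."
            g = ",".join(sorted(e.gradient_labels)) or "."
            fh.write(f"{e.element_id}\t{e.activity_class}\t{r}\t{g}\n")
    with open(out / "rna_directions.tsv", "w") as fh:
        fh.write("gene_id\tmutant\tlevel\n")
        for r in ds.rna:
            fh.write(f"{r.gene_id}\t{r.mutant}\t{r.level}\n")
    (out / "network_genes.txt").write_text("\n".join(ds.network_genes) + "\n")
    (out / "mp_genes.txt").write_text("\n".join(ds.mp_genes) + "\n")

    ds.truth_sites.to_csv(out / "truth" / "sites.tsv", sep="\t", index=False)
    ds.truth_differential.to_csv(
        out / "truth" / "differential.tsv", sep="\t", index=False
    )
    ds.truth_membership.to_csv(
        out / "truth" / "membership.tsv", sep="\t", index=False
    )
    return out


def truth_report(
    ds: SyntheticDataset,
    catalog=None,
    states=None,
    diff_calls=None,
) -> pd.DataFrame:
    """Join planted site truth to pipeline estimates.

    Raises if a required pipeline output is missing, naming the stage.
    Returns one row per planted (bound) site with the matched catalog
    pRE, its estimated occupancy, estimated WT mark flags, and — when
    differential calls are supplied — the per-planted-effect call.
    """
    missing = [
        name
        for name, val in (("catalog", catalog), ("chromatin-state", states))
        if val is None
    ]
    if missing:
        raise ValueError(f"pipeline outputs missing for stages: {missing}")
    from .intervals import IntervalIndex

    index = IntervalIndex((p.interval, p) for p in catalog)
    state_by_id = {s.pre_id: s for s in states}
    call_by_key = {}
    if diff_calls is not None:
        for c in diff_calls:
            call_by_key[(c.mutant, c.pre_id, c.mark)] = c
    rows = []
    bound = ds.truth_sites[ds.truth_sites["k"] >= 1]
    planted = {
        (r["mutant"], r["site_id"], r["mark"]): r["direction"]
        for _, r in ds.truth_differential.iterrows()
    }
    for site in bound.itertuples(index=False):
        probe = GenomicInterval(site.chrom, site.center, site.center + 1)
        hits = index.overlapping(probe)
        pre = hits[0][1] if hits else None
        row = {
            "site_id": site.site_id,
            "true_k": int(site.k),
            "pre_id": pre.pre_id if pre else None,
            "est_k": pre.occupancy.count if pre else None,
        }
        for mark in MARK_ASSAYS:
            row[f"true_{mark}"] = bool(getattr(site, f"mark_{mark}"))
            row[f"est_{mark}"] = (
                state_by_id[pre.pre_id].flag(mark) if pre and pre.pre_id in state_by_id else None
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if diff_calls is not None:
        site_to_pre = dict(zip(df["site_id"], df["pre_id"]))
        drows = []
        for (mutant, site_id, mark), direction in planted.items():
            pre_id = site_to_pre.get(site_id)
            call = call_by_key.get((mutant, pre_id, mark)) if pre_id else None
            drows.append(
                {
                    "mutant": mutant,
                    "site_id": site_id,
                    "mark": mark,
                    "planted": direction,
                    "called": call.call if call else None,
                }
            )
        df.attrs["differential"] = pd.DataFrame(drows)
    return df
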