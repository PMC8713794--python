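"""End-to-end pipeline over a data directory, with a machine-readable report.

Consumes the on-disk layout the simulator writes (and that real data
can be arranged into): ``genes.tsv``, ``peaks/<TF>.bed``,
``peaks/<mark>_WT.bed``, ``coverage/<mark>_<condition>.bedGraph``,
``library_sizes.json``, ``loops_<res>kb.bedpe``, ``enhancers.bed`` +
``enhancer_labels.tsv``, ``rna_directions.tsv``, ``network_genes.txt``,
``mp_genes.txt``.  Missing optional inputs degrade gracefully (no
loops file -> window-only interactome evidence, noted in the report).

A rerun with identical config and inputs is bit-identical; the config
hash is embedded in the summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import activity as activity_mod
from . import catalog as catalog_mod
from . import chromatin as chromatin_mod
from . import differential as diff_mod
from . import enrichment as enrich_mod
from . import interactome as inter_mod
from .intervals import (
    DEFAULT_TFS,
    MARK_ASSAYS,
    read_bedgraph,
    read_bedpe,
    read_gene_table,
    read_peaks_bed,
)
from .reporting import format_fold, percent_int

log = logging.getLogger("preatlas")


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run."""

    data_dir: str
    out_dir: str
    tf_names: tuple = DEFAULT_TFS
    min_occupancy: int = 3
    max_dist: int = 100_000
    min_dist_distal: int = 2500
    fdr: float = 0.01
    resolution: int = 5000
    window_bp: int = 100_000
    tau: float = 1.0
    eps: float = 0.25
    min_rpm: float = 1.0
    ratio_pseudocount: float = 0.5
    alpha: float = 0.01
    n_perm: int = 1000
    seed: int = 0
    mutants: tuple = ("Emx2-KO", "Nr2f1-KO", "Pax6-KO")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the summary report."""
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "notes": [],
    }

    def stage(name):
        log.info("stage %s", name)
        return name

    # -- inputs ----------------------------------------------------------
    name = stage("load")
    try:
        genes = read_gene_table(data / "genes.tsv")
        with open(data / "library_sizes.json") as fh:
            libs = json.load(fh)
        tf_peaks = {
            tf: read_peaks_bed(data / "peaks" / f"{tf}.bed", assay=tf)
            for tf in config.tf_names
        }
        mark_peaks = {
            m: read_peaks_bed(data / "peaks" / f"{m}_WT.bed", assay=m)
            for m in MARK_ASSAYS
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc
    log.info("loaded %d genes, %s TF peak sets", len(genes), len(tf_peaks))

    # -- pRE catalog -----------------------------------------------------
    name = stage("call-pres")
    ranked = catalog_mod.normalize_signal(tf_peaks, libs["tf"])
    pres = catalog_mod.call_pres(ranked)
    spectrum = catalog_mod.occupancy_spectrum(pres, n_tfs=len(config.tf_names))
    catalog_mod.write_catalog(out / "pre_catalog.tsv", pres, config.tf_names)
    report["n_pres"] = len(pres)
    report["occupancy_spectrum"] = {str(k): v for k, v in spectrum.items()}
    log.info("catalog: %d pREs, spectrum %s", len(pres), spectrum)

    # -- interactome -----------------------------------------------------
    name = stage("interactome")
    loops_path = data / f"loops_{config.resolution // 1000}kb.bedpe"
    loops = []
    if loops_path.exists():
        loops = inter_mod.loops_from_bedpe(
            read_bedpe(loops_path), resolution=config.resolution,
            fdr_threshold=config.fdr,
        )
    else:
        report["notes"].append(
            f"no loops file at {loops_path.name}; interactome evidence is "
            f"window-only"
        )
    loci = inter_mod.build_interactome(
        genes, loops, pres,
        window_bp=config.window_bp, resolution=config.resolution,
    )
    inter_mod.write_interactome(out / "interactome.tsv", loci, pres)
    report["n_loops"] = len(loops)
    if loops:
        frac = inter_mod.distal_fraction(
            loops, genes, min_distal_bp=config.min_dist_distal,
            resolution=config.resolution,
        )
        report["distal_fraction_pct"] = percent_int(frac, 1)
    _, tally = inter_mod.count_gene_links(loci, pres, config.min_occupancy)
    report["n_genes_with_combinatorial_pre"] = tally

    # -- enhancer activity ----------------------------------------------
    name = stage("activity")
    enh_bed = data / "enhancers.bed"
    if enh_bed.exists():
        enhancers = activity_mod.read_enhancer_table(
            enh_bed, data / "enhancer_labels.tsv"
        )
        occ = activity_mod.annotate_enhancer_binding(enhancers, tf_peaks)
        comp = activity_mod.class_composition(enhancers, occ)
        comp.to_csv(out / "class_composition.tsv", sep="\t")
        assoc = activity_mod.correlalogram(
            enhancers, occ, alpha=config.alpha, tfs=config.tf_names
        )
        activity_mod.write_correlalogram(out / "correlalogram.tsv", assoc)
        bound_frac = {
            cls: percent_int(
                sum(
                    occ[e.element_id].count >= 1
                    for e in enhancers
                    if e.activity_class == cls
                ),
                max(1, sum(e.activity_class == cls for e in enhancers)),
            )
            for cls in activity_mod.ACTIVITY_CLASSES
        }
        report["enhancer_bound_pct_by_class"] = bound_frac
        report["n_enhancers"] = len(enhancers)
    else:
        report["notes"].append("no enhancer table; activity stage skipped")
        enhancers, occ = [], {}

    # -- network enrichment ----------------------------------------------
    name = stage("enrich-network")
    network_path = data / "network_genes.txt"
    if network_path.exists():
        network = [
            g for g in network_path.read_text().split() if g
        ]
        satisfies = enrich_mod.satisfying_genes(
            genes, pres,
            min_occupancy=config.min_occupancy,
            max_dist=config.max_dist,
            min_dist_distal=config.min_dist_distal,
        )
        enr = enrich_mod.permutation_test(
            network, [g.gene_id for g in genes], satisfies,
            n_perm=config.n_perm, seed=config.seed,
        )
        report["enrichment"] = enr.to_dict()
        report["enrichment_summary"] = enr.summary()
        with open(out / "enrichment.json", "w") as fh:
            json.dump(enr.to_dict(), fh, indent=1)
        log.info("%s", enr.summary())
    else:
        report["notes"].append("no network gene list; enrichment skipped")
        network = []

    # -- chromatin state --------------------------------------------------
    name = stage("chromatin-state")
    states = chromatin_mod.call_states(pres, mark_peaks, condition="WT")
    chromatin_mod.write_states(out / "chromatin_states.tsv", states)
    by_occ = chromatin_mod.mark_by_occupancy(states, pres)
    by_occ.to_csv(out / "mark_by_occupancy.tsv", sep="\t")
    report["mark_by_occupancy"] = {
        str(k): {m: round(v, 1) for m, v in row.items()}
        for k, row in by_occ.iterrows()
    }
    mp_path = data / "mp_genes.txt"
    mp_genes = mp_path.read_text().split() if mp_path.exists() else []
    ratios = chromatin_mod.locus_ratios(
        loci, states, mp_genes, pseudocount=config.ratio_pseudocount
    )
    comparison = chromatin_mod.compare_groups(ratios)
    report["locus_ratio_comparison"] = comparison
    with open(out / "locus_ratios.tsv", "w") as fh:
        fh.write("gene_id\tn_active\tn_repressed\tratio\tgroup\n")
        for r in ratios:
            fh.write(
                f"{r.gene_id}\t{r.n_active_pres}\t{r.n_repressed_pres}\t"
                f"{r.ratio:.4f}\t{r.group}\n"
            )

    # -- differential state -----------------------------------------------
    name = stage("differential")
    rna_path = data / "rna_directions.tsv"
    rna = diff_mod.read_rna_directions(rna_path) if rna_path.exists() else []
    report["differential"] = {}
    report["concordance"] = {}
    all_calls = []
    for mutant in config.mutants:
        calls = []
        for mark in MARK_ASSAYS:
            wt = read_bedgraph(
                data / "coverage" / f"{mark}_WT.bedGraph",
                library_size=libs["tracks"].get(f"{mark}_WT"),
            )
            mut_path = data / "coverage" / f"{mark}_{mutant}.bedGraph"
            if not mut_path.exists():
                report["notes"].append(
                    f"no coverage for {mark} in {mutant}; skipped"
                )
                continue
            mut = read_bedgraph(
                mut_path, library_size=libs["tracks"].get(f"{mark}_{mutant}")
            )
            calls.extend(
                diff_mod.call_differential(
                    pres, wt, mut, mark=mark, mutant=mutant,
                    tau=config.tau, min_rpm=config.min_rpm, eps=config.eps,
                )
            )
        if not calls:
            continue
        all_calls.extend(calls)
        tally = diff_mod.tally_differential(calls, wt_states=states,
                                            catalog_size=len(pres))
        tally.to_csv(out / f"differential_tally_{mutant}.tsv", sep="\t")
        report["differential"][mutant] = {
            mark: {
                "n_assessed": int(row["n_assessed"]),
                "pct_loss": row["pct_loss"],
                "pct_gain": row["pct_gain"],
            }
            for mark, row in tally.iterrows()
        }
        directions = diff_mod.locus_direction(loci, calls, mutant)
        conc = diff_mod.concordance(directions, rna, mutant)
        conc.pop("detail")
        report["concordance"][mutant] = conc
    diff_mod.write_calls(out / "differential_calls.tsv", all_calls)

    # -- report ------------------------------------------------------------
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    (out / "report.txt").write_text(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable run summary."""
    lines = [
        f"pipeline run (config hash {report['config_hash']})",
        f"pRE catalog: {report['n_pres']} elements, occupancy spectrum "
        + ", ".join(
            f"{k}:{v}" for k, v in sorted(report["occupancy_spectrum"].items())
        ),
    ]
    if "distal_fraction_pct" in report:
        lines.append(
            f"loop interactions distal (>= 2.5 kb from TSS): "
            f"{report['distal_fraction_pct']}%"
        )
    if "enrichment" in report:
        e = report["enrichment"]
        lines.append(
            f"network enrichment: {e['observed_count']}/{e['set_size']} "
            f"({e['observed_pct']}%) vs null median {e['null_median']:g} "
            f"({e['null_median_pct']}%): {format_fold(e['fold_rounded'])} "
            f"(empirical P = {e['empirical_p']:.4g})"
        )
    for mutant, conc in report.get("concordance", {}).items():
        if conc["rate_pct"] is not None:
            lines.append(
                f"{mutant}: RNA/epigenome concordance "
                f"{conc['n_matches']}/{conc['n_assessed']} ({conc['rate_pct']}%)"
            )
    for note in report["notes"]:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
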