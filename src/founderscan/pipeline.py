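"""End-to-end orchestration: simulate/load -> QC -> consensus + age ->
iHS scan -> window bootstrap + clusters -> clades -> reports.

A :class:`RunConfig` is the single source of every downstream parameter; it
is serialized next to the outputs as a run manifest so a rerun with the
same manifest reproduces all outputs exactly (stochastic stages receive
per-stage child seeds derived from the one global seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clades import assign_clades
from .founder import AlleleAgeModel, consensus_haplotype
from .hapio import CoreSite, MarkerMap, filter_markers, read_phased_vcf
from .selscan import IhsScan
from .synthdata import SimConfig, core_site_of, emit_vcf, simulate_panel
from .windows import (
    detect_clusters,
    make_windows,
    results_frame,
    stratified_rescan,
    window_bootstrap,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "age", "ihs", "scan", "clades")


@dataclass
class RunConfig:
    """Every knob of the full pipeline, serialized with the outputs."""

    vcf: str | None = None  # input VCF; None => simulate a panel
    core: str | None = None  # "chrom:pos:allele" or "marker_id:allele"
    out_dir: str = "founderscan_out"
    seed: int = 0
    # QC
    call_rate_min: float = 0.95
    hwe_alpha: float = 0.01
    # consensus / age
    support_floor: float = 0.90
    generation_time: float = 30.0
    rate_cM_per_Mb: float = 1.0
    age_n_boot: int = 2000
    # iHS
    truncation_ehh: float = 0.05
    max_gap_bp: int = 200_000
    n_bins: int = 50
    min_bin: int = 20
    # windows / clusters
    window_width_mb: float = 0.25
    window_step_mb: float = 0.20
    scan_n_boot: int = 100_000
    scan_null: str = "sites"  # "sites" (classic iid) or "blocks" (calibrated)
    cluster_threshold: float = 2.5
    cluster_min_sites: int = 3
    cluster_join_gap_bp: int = 200_000
    exclusion_alleles: list = field(default_factory=list)  # [[marker_id, base]]
    # clades
    signature_markers: list | None = None
    clade_patterns: dict | None = None
    run_clades: bool = False
    # simulation (used when vcf is None)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def stage_seeds(seed: int, stages: tuple[str, ...] = STAGES) -> dict[str, int]:
    """Fan one global seed out to independent per-stage child seeds."""
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {
        s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(stages, children)
    }


def run_full(cfg: RunConfig) -> dict:
    """Run the whole pipeline; returns a dict of in-memory results and
    writes per-stage reports plus a manifest under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    results: dict = {"seeds": seeds}

    # --- stage 1: obtain a panel ------------------------------------------
    if cfg.vcf is None:
        sim_cfg = SimConfig(**{**cfg.sim, "seed": seeds["simulate"]})
        hm, mm, truth = simulate_panel(sim_cfg)
        emit_vcf(hm, mm, truth, out / "panel", seed=seeds["simulate"])
        core = core_site_of(mm, sim_cfg.core_marker_id)
        hm.annotate_carriers(core.resolve(mm))
        results["truth"] = truth
    else:
        if cfg.core is None:
            raise ValueError("a core-site spec is required with --vcf")
        core = CoreSite.parse(cfg.core)
        hm, mm, load_report = read_phased_vcf(cfg.vcf, core)
        results["load_report"] = load_report

    # --- stage 2: QC -------------------------------------------------------
    hm, mm, qc_report = filter_markers(
        hm, mm, core, call_rate_min=cfg.call_rate_min, hwe_alpha=cfg.hwe_alpha
    )
    results["qc"] = qc_report
    logger.info("QC: %d/%d markers retained", qc_report.n_retained, qc_report.n_input)

    # --- stage 3: consensus + age -----------------------------------------
    consensus = consensus_haplotype(hm, mm, core, support_floor=cfg.support_floor)
    consensus.to_frame(mm).to_csv(out / "consensus.tsv", sep="\t", index=False)
    age = AlleleAgeModel(
        hm,
        mm,
        core,
        consensus=consensus,
        generation_time=cfg.generation_time,
        rate_cM_per_Mb=cfg.rate_cM_per_Mb,
    ).fit(n_boot=cfg.age_n_boot, seed=seeds["age"])
    age.to_json(out / "age_estimate.json")
    age.per_marker.to_csv(out / "age_per_marker.tsv", sep="\t", index=False)
    results["consensus"] = consensus
    results["age"] = age

    # --- stage 4: iHS scan -------------------------------------------------
    scan = IhsScan(
        hm,
        mm,
        truncation_ehh=cfg.truncation_ehh,
        max_gap_bp=cfg.max_gap_bp,
        n_bins=cfg.n_bins,
        min_bin=cfg.min_bin,
    ).fit()
    scan.to_tsv(out / "ihs.tsv")
    results["ihs"] = scan

    # --- stage 5: windows, bootstrap, clusters, stratified rescan ---------
    pos_mb = mm.pos_bp / 1e6
    windows = make_windows(
        float(np.floor(pos_mb.min() / cfg.window_step_mb) * cfg.window_step_mb),
        float(pos_mb.max()),
        cfg.window_width_mb,
        cfg.window_step_mb,
    )
    if cfg.exclusion_alleles:
        strat = stratified_rescan(
            hm,
            mm,
            [tuple(x) for x in cfg.exclusion_alleles],
            windows,
            n_boot=cfg.scan_n_boot,
            seed=seeds["scan"],
            null=cfg.scan_null,
            scan_kwargs=dict(
                truncation_ehh=cfg.truncation_ehh,
                max_gap_bp=cfg.max_gap_bp,
                n_bins=cfg.n_bins,
                min_bin=cfg.min_bin,
            ),
        )
        wdf = results_frame(strat["with_markers"]).merge(
            results_frame(strat["without_markers"]),
            on=["start_mb", "end_mb"],
            suffixes=("_with", "_without"),
        )
        results["stratified"] = strat
    else:
        wres = window_bootstrap(
            scan.table,
            windows,
            n_boot=cfg.scan_n_boot,
            seed=seeds["scan"],
            null=cfg.scan_null,
        )
        wdf = results_frame(wres)
        results["windows"] = wres
    wdf.to_csv(out / "windows.tsv", sep="\t", index=False)

    clusters = detect_clusters(
        scan.table,
        threshold=cfg.cluster_threshold,
        min_sites=cfg.cluster_min_sites,
        join_gap_bp=cfg.cluster_join_gap_bp,
    )
    with open(out / "clusters.json", "w") as fh:
        json.dump(clusters, fh, indent=2)
    results["clusters"] = clusters

    # --- stage 6: clades (optional; needs signature markers in the map) ---
    if cfg.run_clades:
        ca = assign_clades(hm, mm, cfg.signature_markers, cfg.clade_patterns)
        ca.per_haplotype.to_csv(out / "clades.tsv", sep="\t", index=False)
        results["clades"] = ca

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stage_seeds": seeds,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
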