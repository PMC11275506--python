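"""Forward-time diploid Wright-Fisher simulator with recombination and
selection: the test bed for every analysis module.

The simulator emulates the scenario behind founder-mutation dating and
haplotype-based selection scans: an LD-structured standing panel into which
a single copy of a derived "core" allele is dropped ``founder_age_gen``
generations before sampling, optionally with an additive fitness advantage,
conditioned on the lineage surviving to the present (rejection over fresh
sub-seeds). Ground truth — the founder haplotype, the true age, the
per-generation core-allele trajectory and the carriers at sampling — is
returned alongside the phased panel.

Founding haplotypes come from a first-order template-copying (Li-Stephens
style) process: a small seed set is drawn site-independently at per-site
frequencies f_j ~ background_maf_dist, and each further haplotype is a
mosaic of the haplotypes built before it, keeping its current template
with probability ``ld_decay_rho`` per site and switching to a random
earlier haplotype otherwise. Adjacent-site association decays
geometrically with the switch rate while allele classes retain internal
mosaic diversity, as in real LD-structured panels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "emit_vcf",
    "core_site_of",
    "ascertain_case_control",
]


def ascertain_case_control(
    hm: HaplotypeMatrix,
    core_index: int,
    carrier_fraction: float = 232 / 755,
    seed: int | None = None,
) -> HaplotypeMatrix:
    """Study-style ascertained panel: every carrier sample plus a random
    draw of non-carriers sized so carriers make up ``carrier_fraction`` of
    samples (default mirrors a carrier-enriched case-control cohort of 232
    carriers among 755 participants).

    Haplotype-based selection statistics gain their power from this
    enrichment: a founder allele rare in the population is common in the
    analyzed panel.
    """
    rng = np.random.default_rng(seed)
    geno = hm.entries[:, core_index].reshape(-1, 2)
    car = np.flatnonzero((geno == 1).any(axis=1))
    non = np.flatnonzero(~(geno == 1).any(axis=1))
    if len(car) == 0:
        raise ValueError("no carrier samples to ascertain")
    n_non = int(round(len(car) * (1 - carrier_fraction) / carrier_fraction))
    n_non = min(len(non), max(n_non, 1))
    keep = np.sort(np.concatenate([car, rng.choice(non, n_non, replace=False)]))
    return hm.subset_samples(keep)


def core_site_of(mm: MarkerMap, marker_id: str = "rs_core"):
    """CoreSite spec for a simulated panel's core marker."""
    from .hapio import CoreSite

    j = mm.index_of(marker_id)
    return CoreSite(marker_id, int(mm.pos_bp[j]), str(mm.df["derived"].iloc[j]))


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a 4 Mb, 1000-site panel of 500
    diploids with a neutral 40-generation-old founder allele at the center."""

    n_diploids: int = 500
    n_sites: int = 1000
    region_bp: int = 4_000_000
    recomb_rate: float = 1e-8  # per bp per meiosis = 1 cM/Mb
    founder_age_gen: int = 40
    selection_s: float = 0.0  # fitness 1, 1+s, 1+2s by derived-core genotype
    core_pos_fraction: float = 0.5
    background_maf_low: float = 0.05
    background_maf_high: float = 0.5
    ld_decay_rho: float = 0.9
    penetrance: float = 0.95  # P(affected | carrier); no phenocopies
    min_carrier_copies: int = 1  # survival conditioning threshold at sampling
    max_attempts: int = 2000
    chrom: str = "12"
    core_marker_id: str = "rs_core"
    seed: int = 0

    def __post_init__(self):
        if self.founder_age_gen < 0:
            raise ValueError("founder_age_gen must be >= 0")
        if not (0.0 <= self.selection_s <= 1.0):
            raise ValueError("selection_s must lie in [0, 1]")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")


@dataclass
class SimTruth:
    founder_haplotype: np.ndarray  # 0/1 over all sites at introduction
    true_age_gen: int
    trajectory: list[float]  # derived-core frequency per generation
    carrier_ids: list[str]  # sample ids of carriers at sampling
    selection_s: float
    n_attempts: int
    founder_survived: bool = True

    def to_json(self, path=None) -> dict:
        obj = dict(
            founder_haplotype="".join(map(str, self.founder_haplotype.tolist())),
            true_age_gen=self.true_age_gen,
            trajectory=self.trajectory,
            carrier_ids=self.carrier_ids,
            selection_s=self.selection_s,
            n_attempts=self.n_attempts,
            founder_survived=self.founder_survived,
        )
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2)
        return obj


def _founding_panel(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_hap = 2 * cfg.n_diploids
    n_sites = cfg.n_sites
    f = rng.uniform(cfg.background_maf_low, cfg.background_maf_high, n_sites)
    n_seed = min(20, n_hap)
    H = np.empty((n_hap, n_sites), dtype=np.int8)
    H[:n_seed] = rng.uniform(size=(n_seed, n_sites)) < f
    cols = np.arange(n_sites)
    for i in range(n_seed, n_hap):
        # piecewise-constant template path over sites (first-order mosaic)
        switch = rng.uniform(size=n_sites) >= cfg.ld_decay_rho
        switch[0] = True
        seg = np.cumsum(switch) - 1
        templates = rng.integers(0, i, size=seg[-1] + 1)
        H[i] = H[templates[seg], cols]
    return H


def _positions(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Sorted distinct 1-based site positions with the core at its fraction."""
    core_bp = int(round(cfg.core_pos_fraction * cfg.region_bp))
    need = cfg.n_sites - 1
    draws = rng.integers(1, cfg.region_bp + 1, size=2 * need + 16)
    cand = np.unique(draws)
    cand = cand[cand != core_bp]
    while len(cand) < need:  # vanishingly rare unless sites ~ region size
        extra = rng.integers(1, cfg.region_bp + 1, size=need)
        cand = np.unique(np.concatenate([cand, extra]))
        cand = cand[cand != core_bp]
    pos = np.sort(rng.permutation(cand)[:need])
    pos = np.sort(np.append(pos, core_bp))
    return pos, int(np.searchsorted(pos, core_bp))


def _advance_generation(
    hap: np.ndarray,
    pos: np.ndarray,
    core_index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation: fitness-weighted parents, one gamete per
    offspring chromosome, Poisson-distributed crossovers at uniform bp."""
    n = cfg.n_diploids
    core = hap[:, core_index].reshape(n, 2).sum(axis=1)
    fitness = 1.0 + cfg.selection_s * core
    w = fitness / fitness.sum()

    parents = rng.choice(n, size=2 * n, p=w)  # one parent per gamete
    start_phase = rng.integers(0, 2, size=2 * n)
    n_x = rng.poisson(cfg.recomb_rate * cfg.region_bp, size=2 * n)

    out = np.empty_like(hap)
    plain = n_x == 0
    out[plain] = hap[2 * parents[plain] + start_phase[plain]]
    for g in np.flatnonzero(~plain):
        bp = np.sort(rng.uniform(0, cfg.region_bp, size=n_x[g]))
        cuts = np.searchsorted(pos, bp)  # site index where the phase switches
        phase = start_phase[g]
        gam = np.empty(cfg.n_sites, dtype=hap.dtype)
        bounds = np.concatenate([[0], cuts, [cfg.n_sites]])
        for seg in range(len(bounds) - 1):
            lo, hi = bounds[seg], bounds[seg + 1]
            gam[lo:hi] = hap[2 * parents[g] + phase, lo:hi]
            phase ^= 1
        out[g] = gam
    return out


def _attempt(cfg: SimConfig, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    pos, core_index = _positions(cfg, rng)
    hap = _founding_panel(cfg, rng)
    n_hap = 2 * cfg.n_diploids

    hap[:, core_index] = 0  # core ancestral everywhere at founding
    founder_row = int(rng.integers(0, n_hap))
    hap[founder_row, core_index] = 1
    founder_haplotype = hap[founder_row].copy()

    trajectory = [1.0 / n_hap]
    for _ in range(cfg.founder_age_gen):
        hap = _advance_generation(hap, pos, core_index, cfg, rng)
        freq = float(hap[:, core_index].mean())
        trajectory.append(freq)
        if freq == 0.0:
            return None, pos, core_index, founder_haplotype, trajectory
    if int(round(trajectory[-1] * n_hap)) < cfg.min_carrier_copies:
        return None, pos, core_index, founder_haplotype, trajectory
    return hap, pos, core_index, founder_haplotype, trajectory


def simulate_panel(
    cfg: SimConfig,
) -> tuple[HaplotypeMatrix, MarkerMap, SimTruth]:
    """Simulate a phased diploid panel carrying a founder allele of known age.

    The founder lineage is conditioned on survival by rejection: each
    attempt reruns the whole simulation from a fresh child seed, and the
    attempt count is logged and recorded in the truth object.
    """
    root = np.random.SeedSequence(cfg.seed)
    attempts = 0
    for child in root.spawn(cfg.max_attempts):
        attempts += 1
        hap, pos, core_index, founder_haplotype, trajectory = _attempt(cfg, child)
        if hap is not None:
            break
    else:
        raise RuntimeError(
            f"founder allele lost in all {cfg.max_attempts} attempts at "
            f"s={cfg.selection_s}, age={cfg.founder_age_gen}; increase "
            "selection_s or reduce founder_age_gen"
        )
    if attempts > 1:
        logger.info("founder survived after %d attempts", attempts)

    label_rng = np.random.default_rng(root.generate_state(1)[0] % (2**31))
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_diploids)]
    core_geno = hap[:, core_index].reshape(cfg.n_diploids, 2).sum(axis=1)
    carrier_status = [
        "hom" if c == 2 else "het" if c == 1 else "noncarrier" for c in core_geno
    ]
    affection = [
        "affected"
        if c > 0 and label_rng.uniform() < cfg.penetrance
        else "unaffected"
        for c in core_geno
    ]
    carrier_ids = [s for s, c in zip(sample_ids, core_geno) if c > 0]

    bases_rng = np.random.default_rng(root.generate_state(2)[1] % (2**31))
    anc, der = _draw_alleles(cfg.n_sites, bases_rng)
    mm = MarkerMap(
        pd.DataFrame(
            dict(
                chrom=cfg.chrom,
                pos_bp=pos,
                marker_id=[
                    cfg.core_marker_id if j == core_index else f"rs_sim_{j:05d}"
                    for j in range(cfg.n_sites)
                ],
                ancestral=anc,
                derived=der,
                cM=pos * (cfg.recomb_rate * 1e8) * 1e-6,  # consistent genetic map
            )
        )
    )
    hm = HaplotypeMatrix(hap, sample_ids, carrier_status, affection)
    truth = SimTruth(
        founder_haplotype=founder_haplotype,
        true_age_gen=cfg.founder_age_gen,
        trajectory=trajectory,
        carrier_ids=carrier_ids,
        selection_s=cfg.selection_s,
        n_attempts=attempts,
    )
    return hm, mm, truth


def _draw_alleles(n_sites: int, rng: np.random.Generator):
    """Random distinct (ancestral, derived) base pairs per site."""
    bases = np.array(list("ACGT"))
    anc_idx = rng.integers(0, 4, size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    der_idx = (anc_idx + shift) % 4
    return bases[anc_idx], bases[der_idx]


def emit_vcf(
    hm: HaplotypeMatrix,
    mm: MarkerMap,
    truth: SimTruth | None,
    prefix,
    ref_is_ancestral_prob: float = 0.8,
    seed: int | None = 0,
) -> dict:
    """Write ``prefix.vcf`` (phased GT, AA INFO tag), ``prefix.map.tsv`` and
    ``prefix.truth.json``; byte-stable for identical inputs.

    A fraction of sites (default 20%) is emitted with REF = derived allele
    so that orientation recovery genuinely depends on the AA tag.
    """
    prefix = str(prefix)
    rng = np.random.default_rng(seed)
    flip = rng.uniform(size=hm.n_sites) >= ref_is_ancestral_prob

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##contig=<ID={mm.chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(hm.sample_ids),
    ]
    ent = hm.entries
    df = mm.df
    for j in range(hm.n_sites):
        anc, der = df["ancestral"].iloc[j], df["derived"].iloc[j]
        if flip[j]:
            ref, alt = der, anc  # ALT carries the ancestral base
            col = 1 - ent[:, j]
        else:
            ref, alt = anc, der
            col = ent[:, j]
        gt = "\t".join(
            f"{col[2 * s]}|{col[2 * s + 1]}" for s in range(hm.n_samples)
        )
        lines.append(
            f"{df['chrom'].iloc[j]}\t{df['pos_bp'].iloc[j]}\t"
            f"{df['marker_id'].iloc[j]}\t{ref}\t{alt}\t.\t.\tAA={anc}\tGT\t{gt}"
        )
    vcf_path = prefix + ".vcf"
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    map_path = prefix + ".map.tsv"
    mm.to_tsv(map_path)
    paths = {"vcf": vcf_path, "map": map_path}
    if truth is not None:
        truth_path = prefix + ".truth.json"
        truth.to_json(truth_path)
        paths["truth"] = truth_path
    return paths
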