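"""Overlapping-window summaries of iHS, bootstrap significance, clusters.

Windows tile the scanned region as half-open [start, start + width) Mb
intervals advancing by a step (default 0.25 Mb windows every 0.20 Mb, so
consecutive windows overlap by 50 kb). The per-window statistic is the mean
|iHS| of its sites; its null distribution is built by resampling
size-matched sets of |iHS| values from the chromosome-wide pool excluding
the window's own sites, with the add-one estimator

    p = (1 + #{null >= observed}) / (n_boot + 1)

so p is never exactly zero and is bounded below by 1/(n_boot + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix, MarkerMap

__all__ = [
    "make_windows",
    "window_bootstrap",
    "detect_clusters",
    "stratified_rescan",
    "WindowResult",
]


@dataclass
class WindowResult:
    start_mb: float
    end_mb: float
    n_sites: int
    stat: float  # mean |iHS| in the window (NaN when empty)
    p_boot: float  # NaN when the window is empty
    group_label: str = "all"

    @property
    def empty(self) -> bool:
        return self.n_sites == 0


def make_windows(
    start_mb: float,
    end_mb: float,
    width_mb: float = 0.25,
    step_mb: float = 0.20,
) -> list[tuple[float, float]]:
    """Half-open [start, start+width) tiles advancing by step until end_mb
    is covered (the last window may overhang)."""
    if end_mb <= start_mb:
        raise ValueError("end_mb must exceed start_mb")
    if width_mb <= 0 or step_mb <= 0:
        raise ValueError("width and step must be positive")
    windows = []
    s = start_mb
    while True:
        windows.append((round(s, 10), round(s + width_mb, 10)))
        if s + width_mb >= end_mb - 1e-12:
            break
        s += step_mb
    return windows


def window_stat(values: np.ndarray, kind: str = "mean_abs", threshold: float = 2.5):
    if kind == "mean_abs":
        return float(np.abs(values).mean())
    if kind == "prop_above":
        return float((np.abs(values) > threshold).mean())
    raise ValueError(f"unknown window statistic {kind!r}")


def window_bootstrap(
    table: pd.DataFrame,
    windows: list[tuple[float, float]],
    n_boot: int = 100_000,
    seed: int | None = None,
    stat: str = "mean_abs",
    threshold: float = 2.5,
    group_label: str = "all",
    null: str = "sites",
) -> list[WindowResult]:
    """Bootstrap p-value for each window's statistic against the
    chromosome-wide |iHS| pool.

    ``null="sites"`` resamples k individual values with replacement from
    the pool excluding the window's own sites — the classic chromosome-wide
    iHS bootstrap. Because neighbouring iHS values are correlated, this
    null is anti-conservative for window means wherever LD is appreciable.
    ``null="blocks"`` instead places k *contiguous* scorable sites at
    random (circular) positions along the chromosome, preserving the local
    correlation structure; under neutrality its p-values are calibrated by
    construction (window placement is exchangeable).
    """
    rng = np.random.default_rng(seed)
    scor = table[table["scorable"]].sort_values("pos_bp")
    pos_mb = scor["pos_bp"].to_numpy() / 1e6
    vals = np.abs(scor["ihs"].to_numpy(dtype=float))
    if null not in ("sites", "blocks"):
        raise ValueError("null must be 'sites' or 'blocks'")

    results = []
    for start, end in windows:
        inside = (pos_mb >= start) & (pos_mb < end)
        k = int(inside.sum())
        if k == 0:
            results.append(
                WindowResult(start, end, 0, np.nan, np.nan, group_label)
            )
            continue
        obs = window_stat(vals[inside], stat, threshold)
        if null == "sites":
            pool = vals[~inside]
            if len(pool) == 0:
                results.append(
                    WindowResult(start, end, k, obs, np.nan, group_label)
                )
                continue
            draws = pool[rng.integers(0, len(pool), size=(n_boot, k))]
        else:
            m = len(vals)
            starts = rng.integers(0, m, size=n_boot)
            draws = vals[(starts[:, None] + np.arange(k)[None, :]) % m]
        null_stats = (
            draws.mean(axis=1)
            if stat == "mean_abs"
            else (draws > threshold).mean(axis=1)
        )
        p = (1 + int((null_stats >= obs - 1e-15).sum())) / (n_boot + 1)
        results.append(WindowResult(start, end, k, obs, p, group_label))
    return results


def detect_clusters(
    table: pd.DataFrame,
    threshold: float = 2.5,
    min_sites: int = 3,
    join_gap_bp: int = 200_000,
) -> list[dict]:
    """Maximal runs of sites with |iHS| > threshold, merged across gaps
    smaller than ``join_gap_bp``, reported as bp intervals."""
    scor = table[table["scorable"]].sort_values("pos_bp")
    hits = scor[np.abs(scor["ihs"]) > threshold]
    if hits.empty:
        return []
    pos = hits["pos_bp"].to_numpy()
    clusters = []
    run_start = run_prev = pos[0]
    count = 1
    for p in pos[1:]:
        if p - run_prev < join_gap_bp:
            run_prev = p
            count += 1
        else:
            clusters.append((run_start, run_prev, count))
            run_start = run_prev = p
            count = 1
    clusters.append((run_start, run_prev, count))
    return [
        dict(start_bp=int(s), end_bp=int(e), n_sites=int(c))
        for s, e, c in clusters
        if c >= min_sites
    ]


def results_frame(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                start_mb=r.start_mb,
                end_mb=r.end_mb,
                n_sites=r.n_sites,
                stat=r.stat,
                p_boot=r.p_boot,
                group=r.group_label,
            )
            for r in results
        ]
    )


def exclusion_mask(
    hm: HaplotypeMatrix,
    mm: MarkerMap,
    exclusion_alleles: list[tuple[str, str]],
) -> np.ndarray:
    """Boolean mask over chromosomes carrying any exclusion allele.

    Each exclusion is ``(marker_id, base)``; the base is translated to the
    0/1 coding through the marker map's ancestral/derived columns.
    """
    mask = np.zeros(hm.n_chromosomes, dtype=bool)
    for marker_id, base in exclusion_alleles:
        j = mm.index_of(marker_id)
        row = mm.df.iloc[j]
        if base == row["derived"]:
            code = 1
        elif base == row["ancestral"]:
            code = 0
        else:
            raise ValueError(
                f"allele {base!r} matches neither allele of {marker_id}"
            )
        mask |= hm.entries[:, j] == code
    return mask


def stratified_rescan(
    hm: HaplotypeMatrix,
    mm: MarkerMap,
    exclusion_alleles: list[tuple[str, str]],
    windows: list[tuple[float, float]],
    n_boot: int = 100_000,
    seed: int | None = None,
    scan_kwargs: dict | None = None,
    null: str = "sites",
) -> dict:
    """Re-run the full iHS + window pipeline after removing chromosomes
    that carry any exclusion allele (e.g. inflammatory-disease tag SNPs),
    and report the paired with/without window results plus mean +- SD iHS
    per subset.

    Exclusion is per chromosome (haplotype), not per sample: the affected
    phase alone is dropped. Raises if fewer than 10 chromosomes remain.
    """
    from .selscan import IhsScan

    scan_kwargs = scan_kwargs or {}
    mask = exclusion_mask(hm, mm, exclusion_alleles)
    keep = np.flatnonzero(~mask)
    if len(keep) < 10:
        raise ValueError(
            f"exclusion leaves {len(keep)} chromosomes (< 10); aborting"
        )

    full = IhsScan(hm, mm, **scan_kwargs).fit()
    # common random numbers across the paired bootstraps: the with/without
    # comparison is paired, and identity inputs give identical outputs
    boot_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))

    # exclusion is per chromosome, so phases stop pairing into diploids;
    # the rescan runs on a haplotype-level (haploid) view of the survivors
    chrom_ids = np.asarray(hm.chrom_ids)[keep]
    sub = HaplotypeMatrix.from_haplotypes(hm.entries[keep], chrom_ids.tolist())
    reduced = IhsScan(sub, mm, **scan_kwargs).fit()

    res_full = window_bootstrap(
        full.table, windows, n_boot=n_boot, seed=boot_seed,
        group_label="with_markers", null=null,
    )
    res_red = window_bootstrap(
        reduced.table, windows, n_boot=n_boot, seed=boot_seed,
        group_label="without_markers", null=null,
    )

    def _mean_sd(result):
        v = np.abs(result.scorable["ihs"].to_numpy())
        return dict(mean_abs_ihs=float(v.mean()), sd_abs_ihs=float(v.std(ddof=1)))

    return dict(
        with_markers=res_full,
        without_markers=res_red,
        n_excluded=int(mask.sum()),
        n_retained=int(len(keep)),
        summary={
            "with_markers": _mean_sd(full),
            "without_markers": _mean_sd(reduced),
        },
        scan_with=full,
        scan_without=reduced,
    )
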