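"""Extended haplotype homozygosity (EHH), integrated areas, and iHS.

For a core site and an allele class (chromosomes carrying the ancestral or
the derived allele), EHH at a site j on one side of the core is the
probability that two chromosomes drawn at random from the class are
identical over every site between the core and j:

    EHH_j = sum_h C(n_h, 2) / C(n, 2)

over the partition of the class into distinct extended haplotypes. The curve
starts at 1 at the core and is nonincreasing outward; extension stops when
it drops below a truncation threshold (0.05 by default), at the chromosome
end, or across an inter-marker gap larger than ``max_gap_bp``.

iHHA / iHHD are the trapezoidal areas under the ancestral / derived curves
(left + right), integrated against genetic distance when the map carries cM
positions, else physical distance in Mb. The unstandardized score
ln(iHHA/iHHD) is then z-scored within derived-allele-frequency bins across
the chromosome so the final iHS has mean 0 and variance 1 in every bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix, MarkerMap

try:  # optional compiled kernel; the numpy path below is the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "EhhCurve",
    "ehh",
    "integrate_ihh",
    "unstandardized_ihs",
    "standardize_ihs",
    "IhsScan",
    "IhsScanResult",
]

ANCESTRAL, DERIVED = 0, 1


@dataclass
class EhhCurve:
    """EHH decay in one direction from a core site for one allele class."""

    core_index: int
    allele_class: int  # 0 ancestral, 1 derived
    direction: int  # -1 left, +1 right
    site_indices: np.ndarray  # visited sites, starting at the core
    pos_bp: np.ndarray
    ehh: np.ndarray  # EHH at each visited site; ehh[0] == 1
    truncation: str  # "threshold" | "chromosome-end" | "gap"


def _ehh_walk_numpy(sub, core_index, direction, truncation_ehh, pos_bp, max_gap_bp):
    """Reference extension walk; returns (site list, ehh list, stop reason)."""
    n, n_sites = sub.shape
    sites = [core_index]
    curve = [1.0]
    active = np.arange(n)
    group_ids = np.zeros(n, dtype=np.int64)
    denom = n * (n - 1)
    truncation = "chromosome-end"
    j = core_index
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= n_sites:
            truncation = "chromosome-end"
            break
        if (
            max_gap_bp is not None
            and abs(int(pos_bp[j_next]) - int(pos_bp[j])) > max_gap_bp
        ):
            truncation = "gap"
            break
        j = j_next
        t = group_ids * 2 + sub[active, j]
        c = np.bincount(t)
        e = float((c * (c - 1)).sum() / denom)
        sites.append(j)
        curve.append(e)
        if e < truncation_ehh:
            truncation = "threshold"
            break
        big = c >= 2
        keep = big[t]
        remap = np.cumsum(big) - 1  # survivor bins -> compact new ids
        group_ids = remap[t[keep]]
        active = active[keep]
    return sites, curve, truncation


if _HAVE_NUMBA:

    @njit(cache=True)
    def _ehh_walk_jit(sub, core_index, direction, truncation_ehh, pos_bp, max_gap_bp):
        n, n_sites = sub.shape
        max_steps = n_sites
        out_sites = np.empty(max_steps + 1, np.int64)
        out_ehh = np.empty(max_steps + 1, np.float64)
        out_sites[0] = core_index
        out_ehh[0] = 1.0
        m = 1
        active = np.arange(n)
        group_ids = np.zeros(n, np.int64)
        n_active = n
        denom = n * (n - 1)
        counts = np.zeros(2 * n + 2, np.int64)
        stop = 0  # 0 chromosome-end, 1 gap, 2 threshold
        j = core_index
        while True:
            j_next = j + direction
            if j_next < 0 or j_next >= n_sites:
                stop = 0
                break
            if max_gap_bp >= 0 and abs(pos_bp[j_next] - pos_bp[j]) > max_gap_bp:
                stop = 1
                break
            j = j_next
            pairs = 0
            hi = 0
            for i in range(n_active):
                t = group_ids[i] * 2 + sub[active[i], j]
                group_ids[i] = t
                counts[t] += 1
                if t > hi:
                    hi = t
            for t in range(hi + 1):
                c = counts[t]
                if c > 1:
                    pairs += c * (c - 1)
            e = pairs / denom
            out_sites[m] = j
            out_ehh[m] = e
            m += 1
            if e < truncation_ehh:
                stop = 2
                break
            # compact: drop singleton groups, renumber survivors
            new_id = 0
            for t in range(hi + 1):
                if counts[t] >= 2:
                    counts[t] = -2 - new_id  # mark with new id
                    new_id += 1
            k = 0
            for i in range(n_active):
                c = counts[group_ids[i]]
                if c <= -2:
                    active[k] = active[i]
                    group_ids[k] = -2 - c
                    k += 1
            for t in range(hi + 1):
                counts[t] = 0
            n_active = k
        return out_sites[:m], out_ehh[:m], stop


def ehh(
    hm: HaplotypeMatrix,
    core_index: int,
    allele_class: int,
    direction: int,
    truncation_ehh: float = 0.05,
    max_gap_bp: int | None = 200_000,
    pos_bp: np.ndarray | None = None,
) -> EhhCurve:
    """EHH curve in one direction from the core for one allele class.

    Haplotype partitions are refined incrementally: each extension site
    splits every existing group by the allele carried there, so the curve is
    computed in O(extension length x class size).
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 (left) or +1 (right)")
    ent = hm.entries
    if pos_bp is None:
        pos_bp = np.arange(ent.shape[1])
    rows = np.flatnonzero(ent[:, core_index] == allele_class)
    n = len(rows)
    if n < 2:
        raise ValueError(
            f"allele class {allele_class} has {n} chromosome(s) at site "
            f"{core_index}; EHH needs >= 2"
        )
    sub = np.ascontiguousarray(ent[rows])

    if _HAVE_NUMBA:
        site_arr, ehh_arr, stop = _ehh_walk_jit(
            sub,
            np.int64(core_index),
            np.int64(direction),
            float(truncation_ehh),
            np.asarray(pos_bp, dtype=np.int64),
            np.int64(-1 if max_gap_bp is None else max_gap_bp),
        )
        truncation = ("chromosome-end", "gap", "threshold")[stop]
        sites = site_arr.tolist()
        curve = ehh_arr
    else:  # pragma: no cover - exercised only without numba
        sites, curve, truncation = _ehh_walk_numpy(
            sub, core_index, direction, truncation_ehh, pos_bp, max_gap_bp
        )
    return EhhCurve(
        core_index=core_index,
        allele_class=allele_class,
        direction=direction,
        site_indices=np.asarray(sites),
        pos_bp=np.asarray([pos_bp[s] for s in sites]),
        ehh=np.asarray(curve, dtype=float),
        truncation=truncation,
    )


def integrate_ihh(
    curve: EhhCurve,
    distance: np.ndarray | None = None,
    truncation_ehh: float = 0.05,
) -> float:
    """Trapezoidal area under one EHH curve against distance.

    ``distance`` gives the integration coordinate per visited site (cM, or
    Mb for physical maps); defaults to ``pos_bp`` scaled to Mb. When the
    curve's final segment crosses the truncation threshold, the area is
    included only down to the crossing point, located by linear
    interpolation — the sub-threshold remainder contributes nothing.
    """
    x = (
        np.abs(curve.pos_bp - curve.pos_bp[0]) / 1e6
        if distance is None
        else np.abs(np.asarray(distance, dtype=float) - float(distance[0]))
    )
    y = curve.ehh
    if len(y) == 1:
        return 0.0
    if curve.truncation == "threshold" and y[-1] < truncation_ehh and len(y) >= 2:
        y0, y1 = y[-2], y[-1]
        x0, x1 = x[-2], x[-1]
        frac = (y0 - truncation_ehh) / (y0 - y1) if y0 > y1 else 1.0
        x = np.concatenate([x[:-1], [x0 + frac * (x1 - x0)]])
        y = np.concatenate([y[:-1], [truncation_ehh]])
    return float(np.trapezoid(y, x))


def unstandardized_ihs(iHHA: float, iHHD: float) -> float:
    """ln(iHHA / iHHD); positive for long ancestral, negative for long
    derived haplotypes. Both areas must be strictly positive."""
    if iHHA <= 0.0 or iHHD <= 0.0:
        raise ValueError("iHH areas must be positive; mark the site unscorable")
    return float(np.log(iHHA / iHHD))


def standardize_ihs(
    table: pd.DataFrame,
    n_bins: int = 50,
    min_bin: int = 20,
) -> pd.DataFrame:
    """Standardize uihs within derived-allele-frequency bins.

    Sites are binned by ``p`` into ``n_bins`` equal-width bins on (0, 1);
    adjacent bins are merged left-to-right until every occupied bin holds at
    least ``min_bin`` scorable sites; within each bin
    ``ihs = (uihs - mean) / SD`` with the population SD. Bins with zero SD
    leave their sites unscorable (``ihs`` NaN, ``scorable`` False).

    Returns a copy with columns ``ihs`` and ``freq_bin`` added.
    """
    out = table.copy()
    out["ihs"] = np.nan
    scor = out["scorable"].to_numpy(dtype=bool) & np.isfinite(
        out["uihs"].to_numpy(dtype=float)
    )
    n_scor = int(scor.sum())
    if n_scor < min_bin:
        raise ValueError(
            f"{n_scor} scorable sites < min_bin={min_bin}; cannot standardize"
        )
    p = out["p"].to_numpy(dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    raw_bin = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, n_bins - 1)

    # merge adjacent raw bins until each merged bin holds >= min_bin sites
    counts = np.bincount(raw_bin[scor], minlength=n_bins)
    merged = np.zeros(n_bins, dtype=int)
    label, acc = 0, 0
    for b in range(n_bins):
        merged[b] = label
        acc += counts[b]
        if acc >= min_bin:
            label += 1
            acc = 0
    if acc > 0:  # fold a trailing underfull bin into the previous label
        merged[merged == label] = max(label - 1, 0)
    bin_of = merged[raw_bin]
    out["freq_bin"] = bin_of

    uihs = out["uihs"].to_numpy(dtype=float)
    for b in np.unique(bin_of[scor]):
        m = scor & (bin_of == b)
        vals = uihs[m]
        mu = vals.mean()
        sd = vals.std()  # population SD
        if sd <= 1e-12 * max(1.0, abs(mu)):  # constant bin up to roundoff
            out.loc[m, "scorable"] = False
            continue
        out.loc[m, "ihs"] = (vals - mu) / sd
    return out


@dataclass
class IhsScanResult:
    """Per-site iHS table plus standardization bin statistics."""

    table: pd.DataFrame
    bin_stats: pd.DataFrame
    n_chromosomes: int
    truncation_ehh: float

    @property
    def scorable(self) -> pd.DataFrame:
        return self.table[self.table["scorable"]]

    def summary(self) -> str:
        t = self.scorable
        lines = [
            "iHS scan",
            "=" * 46,
            f"chromosomes              {self.n_chromosomes}",
            f"sites scored / total     {len(t)} / {len(self.table)}",
            f"EHH truncation           {self.truncation_ehh}",
            f"mean |iHS| (SD)          {t['ihs'].abs().mean():.2f}"
            f" ({t['ihs'].abs().std(ddof=1):.2f})",
            f"sites with |iHS| > 2.5   {(t['ihs'].abs() > 2.5).sum()}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["marker_id", "pos_bp", "p", "iHHA", "iHHD", "uihs", "ihs", "scorable"]
        self.table[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot(self, ax=None, threshold: float = 2.5):
        """|iHS| against genomic position, threshold line marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        t = self.scorable
        ax.scatter(t["pos_bp"] / 1e6, t["ihs"].abs(), s=6, alpha=0.6)
        ax.axhline(threshold, color="crimson", lw=1, ls="--")
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("|iHS|")
        return ax


class IhsScan:
    """Chromosome-wide iHS scan over a complete phased panel.

    Parameters
    ----------
    hm, mm
        Complete haplotype matrix and its marker map.
    truncation_ehh
        EHH level at which curve extension stops (default 0.05).
    max_gap_bp
        Inter-marker gap beyond which extension stops (default 200 kb).
    n_bins, min_bin
        Frequency-bin scheme for standardization.

    ``fit`` computes, for every scorable site (derived-allele count between
    2 and n-2), the four EHH curves (both alleles x both directions), the
    areas iHHA / iHHD, the unstandardized score and the bin-standardized
    iHS.
    """

    def __init__(
        self,
        hm: HaplotypeMatrix,
        mm: MarkerMap,
        truncation_ehh: float = 0.05,
        max_gap_bp: int = 200_000,
        n_bins: int = 50,
        min_bin: int = 20,
    ):
        if not hm.is_complete:
            raise ValueError("iHS scan requires a complete (QC-filtered) matrix")
        if hm.n_sites != len(mm):
            raise ValueError("matrix and marker map disagree on site count")
        self.hm = hm
        self.mm = mm
        self.truncation_ehh = float(truncation_ehh)
        self.max_gap_bp = int(max_gap_bp)
        self.n_bins = int(n_bins)
        self.min_bin = int(min_bin)

    def _distance(self) -> np.ndarray:
        cm = self.mm.cM
        if cm is not None:
            return cm
        return self.mm.pos_bp / 1e6

    def fit(self) -> IhsScanResult:
        hm, mm = self.hm, self.mm
        ent = hm.entries
        n = hm.n_chromosomes
        pos = mm.pos_bp
        dist = self._distance()
        derived_count = (ent == 1).sum(axis=0)
        p = derived_count / n

        records = []
        for j in range(hm.n_sites):
            rec = dict(
                marker_id=mm.marker_ids.iloc[j],
                pos_bp=int(pos[j]),
                p=float(p[j]),
                iHHA=np.nan,
                iHHD=np.nan,
                uihs=np.nan,
                scorable=False,
            )
            if 2 <= derived_count[j] <= n - 2:
                areas = {}
                ok = True
                for cls in (ANCESTRAL, DERIVED):
                    total = 0.0
                    for direction in (-1, 1):
                        c = ehh(
                            hm,
                            j,
                            cls,
                            direction,
                            truncation_ehh=self.truncation_ehh,
                            max_gap_bp=self.max_gap_bp,
                            pos_bp=pos,
                        )
                        total += integrate_ihh(
                            c,
                            distance=dist[c.site_indices],
                            truncation_ehh=self.truncation_ehh,
                        )
                    areas[cls] = total
                    if total <= 0.0:
                        ok = False
                rec["iHHA"] = areas[ANCESTRAL]
                rec["iHHD"] = areas[DERIVED]
                if ok:
                    rec["uihs"] = unstandardized_ihs(areas[ANCESTRAL], areas[DERIVED])
                    rec["scorable"] = True
            records.append(rec)

        table = pd.DataFrame(records)
        table = standardize_ihs(table, n_bins=self.n_bins, min_bin=self.min_bin)

        scor = table[table["scorable"]]
        bin_stats = (
            scor.groupby("freq_bin")
            .agg(
                p_min=("p", "min"),
                p_max=("p", "max"),
                n=("uihs", "size"),
                E_p=("uihs", "mean"),
                SD_p=("uihs", lambda v: float(np.std(v))),
            )
            .reset_index()
        )
        return IhsScanResult(
            table=table,
            bin_stats=bin_stats,
            n_chromosomes=n,
            truncation_ehh=self.truncation_ehh,
        )
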