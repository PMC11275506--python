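"""Haplotype/marker data model, phased-VCF and tabular I/O, and marker QC.

The in-memory containers are deliberately thin: a :class:`HaplotypeMatrix` is a
``(2*n_samples, n_sites)`` int8 array of 0 (ancestral) / 1 (derived) calls with
sample/phase provenance, and a :class:`MarkerMap` is a pandas DataFrame wrapper
holding the coordinate authority for every distance computation downstream.

Missingness (coded -1) exists only between loading and :func:`filter_markers`;
every analysis module requires a complete matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

MISSING = -1

MAP_COLUMNS = ["chrom", "pos_bp", "marker_id", "ancestral", "derived"]
OPTIONAL_MAP_COLUMNS = ["cM", "r2", "impute_acc"]


class MarkerMap:
    """Per-site coordinates and allele orientation for one chromosome.

    Wraps a DataFrame with columns ``chrom, pos_bp, marker_id, ancestral,
    derived`` and optional ``cM`` (genetic position), ``r2``, ``impute_acc``.
    Positions are 1-based and strictly increasing; ancestral/derived bases
    differ at every site.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        df = df.reset_index(drop=True)
        pos = df["pos_bp"].to_numpy()
        if len(df) == 0:
            raise ValueError("empty marker map")
        if df["chrom"].nunique() > 1:
            raise ValueError("marker map must describe a single chromosome")
        if np.any(pos[1:] <= pos[:-1]):
            raise ValueError("pos_bp must be strictly increasing")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker_id: {dup}")
        if (df["ancestral"] == df["derived"]).any():
            raise ValueError("ancestral and derived alleles must differ")
        if "cM" in df.columns and df["cM"].notna().all():
            cm = df["cM"].to_numpy(dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError("cM must be nondecreasing with pos_bp")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def pos_bp(self) -> np.ndarray:
        return self.df["pos_bp"].to_numpy()

    @property
    def marker_ids(self) -> pd.Series:
        return self.df["marker_id"]

    @property
    def chrom(self) -> str:
        return str(self.df["chrom"].iloc[0])

    @property
    def cM(self) -> np.ndarray | None:
        if "cM" in self.df.columns and self.df["cM"].notna().all():
            return self.df["cM"].to_numpy(dtype=float)
        return None

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.df["marker_id"] == marker_id).to_numpy())
        if len(hits) != 1:
            raise KeyError(f"marker {marker_id!r} not found")
        return int(hits[0])

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.df.iloc[np.asarray(idx)].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


@dataclass
class CoreSite:
    """The designated core marker and its derived allele (e.g. the LRRK2
    p.G2019S site rs34637584, derived allele A, GRCh38 chr12:40340400)."""

    marker_id: str | None
    pos_bp: int | None
    derived_allele: str

    def resolve(self, mm: MarkerMap) -> int:
        """Return the unique marker-map column index of the core site."""
        df = mm.df
        if self.marker_id is not None:
            mask = (df["marker_id"] == self.marker_id).to_numpy()
        elif self.pos_bp is not None:
            mask = (df["pos_bp"] == self.pos_bp).to_numpy()
        else:
            raise ValueError("core site needs a marker_id or pos_bp")
        hits = np.flatnonzero(mask)
        if len(hits) != 1:
            raise ValueError(
                f"core site {self.marker_id or self.pos_bp} resolves to "
                f"{len(hits)} markers (need exactly 1)"
            )
        i = int(hits[0])
        row = df.iloc[i]
        if self.derived_allele not in (row["ancestral"], row["derived"]):
            raise ValueError(
                f"core derived allele {self.derived_allele!r} matches neither "
                f"allele of {row['marker_id']}"
            )
        return i

    @classmethod
    def parse(cls, spec: str) -> "CoreSite":
        """Parse ``chrom:pos:allele`` or ``marker_id:allele``."""
        parts = spec.split(":")
        if len(parts) == 3:
            return cls(marker_id=None, pos_bp=int(parts[1]), derived_allele=parts[2])
        if len(parts) == 2:
            return cls(marker_id=parts[0], pos_bp=None, derived_allele=parts[1])
        raise ValueError(f"cannot parse core-site spec {spec!r}")


@dataclass
class HaplotypeMatrix:
    """Phased chromosomes x sites, coded 0 = ancestral, 1 = derived.

    Rows are ordered (sample0, phase0), (sample0, phase1), (sample1, phase0),
    ... ``carrier_status`` is per sample: ``"het"``, ``"hom"`` or
    ``"noncarrier"``; ``affection`` is ``"affected"`` / ``"unaffected"``.
    """

    entries: np.ndarray
    sample_ids: list[str]
    carrier_status: list[str] = field(default_factory=list)
    affection: list[str] = field(default_factory=list)
    haploid: bool = False  # True: one row per sample (chromosome-level view)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be 2-D")
        rows_per_sample = 1 if self.haploid else 2
        if self.entries.shape[0] != rows_per_sample * len(self.sample_ids):
            raise ValueError(f"row count must be {rows_per_sample} x n_samples")
        if not self.carrier_status:
            self.carrier_status = ["noncarrier"] * len(self.sample_ids)
        if not self.affection:
            self.affection = ["unaffected"] * len(self.sample_ids)
        bad = ~np.isin(self.entries, (0, 1, MISSING))
        if bad.any():
            raise ValueError("entries must be 0, 1 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_chromosomes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sites(self) -> int:
        return self.entries.shape[1]

    @property
    def phase_index(self) -> np.ndarray:
        if self.haploid:
            return np.zeros(self.n_samples, dtype=int)
        return np.tile([0, 1], self.n_samples)

    @property
    def chrom_ids(self) -> list[str]:
        if self.haploid:
            return list(self.sample_ids)
        return [f"{s}_{p}" for s in self.sample_ids for p in (0, 1)]

    @classmethod
    def from_haplotypes(
        cls, entries: np.ndarray, chrom_ids: list[str] | None = None
    ) -> "HaplotypeMatrix":
        """Chromosome-level view: one row per haplotype, no diploid pairing."""
        entries = np.asarray(entries, dtype=np.int8)
        if chrom_ids is None:
            chrom_ids = [f"hap{i}" for i in range(entries.shape[0])]
        return cls(entries, list(chrom_ids), haploid=True)

    @property
    def is_complete(self) -> bool:
        return not (self.entries == MISSING).any()

    def sample_of_row(self, row: int) -> int:
        return row // 2

    def carrier_rows(self, core_index: int) -> np.ndarray:
        """Row indices of chromosomes bearing the derived allele at the core.

        For a heterozygote this is the single phase carrying the mutation;
        for a homozygote, both phases.
        """
        return np.flatnonzero(self.entries[:, core_index] == 1)

    def noncarrier_rows(self, core_index: int) -> np.ndarray:
        """Chromosome rows of samples carrying no derived core allele.

        Carrier samples' in-trans chromosomes are excluded: non-carrier
        frequencies are estimated from unrelated non-carrier individuals.
        """
        if self.haploid:
            return np.flatnonzero(self.entries[:, core_index] == 0)
        geno = self.entries[:, core_index].reshape(-1, 2)
        nc_samples = np.flatnonzero((geno == 1).sum(axis=1) == 0)
        return np.sort(np.concatenate([2 * nc_samples, 2 * nc_samples + 1]))

    def annotate_carriers(self, core_index: int) -> None:
        if self.haploid:
            self.carrier_status = [
                "het" if a == 1 else "noncarrier"
                for a in self.entries[:, core_index]
            ]
            return
        geno = self.entries[:, core_index].reshape(-1, 2)
        counts = (geno == 1).sum(axis=1)
        self.carrier_status = [
            ("hom" if c == 2 else "het" if c == 1 else "noncarrier") for c in counts
        ]

    def subset_samples(self, keep: np.ndarray) -> "HaplotypeMatrix":
        """New matrix restricted to the given sample indices (both phases)."""
        keep = np.asarray(keep)
        if self.haploid:
            return HaplotypeMatrix(
                self.entries[keep],
                [self.sample_ids[i] for i in keep],
                [self.carrier_status[i] for i in keep],
                [self.affection[i] for i in keep],
                haploid=True,
            )
        rows = np.empty(2 * len(keep), dtype=int)
        rows[0::2], rows[1::2] = 2 * keep, 2 * keep + 1
        return HaplotypeMatrix(
            self.entries[rows],
            [self.sample_ids[i] for i in keep],
            [self.carrier_status[i] for i in keep],
            [self.affection[i] for i in keep],
        )

    def subset_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.entries[:, np.asarray(idx)],
            list(self.sample_ids),
            list(self.carrier_status),
            list(self.affection),
        )

    def subset_chromosomes(self, rows: np.ndarray) -> np.ndarray:
        return self.entries[np.asarray(rows)]


# ---------------------------------------------------------------------------
# VCF / tabular I/O
# ---------------------------------------------------------------------------


def read_phased_vcf(path, core: CoreSite) -> tuple[HaplotypeMatrix, MarkerMap, dict]:
    """Load a phased single-chromosome VCF into (HaplotypeMatrix, MarkerMap).

    Only biallelic SNVs with fully phased GT fields (``|`` separator) are
    retained; dropped records are counted in the returned report. Alleles are
    recoded to ancestral(0)/derived(1) using the AA INFO tag when present;
    otherwise REF is treated as ancestral and a loud warning is emitted,
    because the sign of iHS depends on the orientation.

    Returns ``(hm, mm, report)`` where report counts
    ``{"unphased", "multiallelic", "non_snv", "aa_fallback"}`` records.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains zero samples")

    report = {"unphased": 0, "multiallelic": 0, "non_snv": 0, "aa_fallback": 0}
    columns: list[np.ndarray] = []
    rows: list[dict] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            report["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            report["non_snv"] += 1
            continue
        gts = rec.genotypes  # [a0, a1, phased] per sample
        calls = np.full(2 * len(samples), MISSING, dtype=np.int8)
        unphased = False
        for si, (a0, a1, phased) in enumerate(gts):
            if a0 >= 0 and a1 >= 0 and not phased and a0 != a1:
                unphased = True
                break
            calls[2 * si] = a0 if a0 >= 0 else MISSING
            calls[2 * si + 1] = a1 if a1 >= 0 else MISSING
        if unphased:
            report["unphased"] += 1
            continue

        aa = rec.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
        if aa == alt:
            ancestral, derived = alt, ref
            obs = calls >= 0
            calls[obs] = 1 - calls[obs]  # flip: ALT is ancestral
        elif aa == ref or aa is None:
            if aa is None:
                report["aa_fallback"] += 1
            ancestral, derived = ref, alt
        else:
            # AA neither allele: fall back to REF-as-ancestral
            report["aa_fallback"] += 1
            ancestral, derived = ref, alt
        columns.append(calls)
        rows.append(
            dict(
                chrom=str(rec.CHROM),
                pos_bp=rec.POS,
                marker_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ancestral=ancestral,
                derived=derived,
            )
        )
    if report["aa_fallback"]:
        logger.warning(
            "AA INFO tag absent/invalid for %d sites: REF treated as ancestral; "
            "iHS sign depends on this orientation",
            report["aa_fallback"],
        )
    if not rows:
        raise ValueError("no phased biallelic SNVs in VCF")

    mm = MarkerMap(pd.DataFrame(rows))
    hm = HaplotypeMatrix(np.column_stack(columns), samples)
    core_index = core.resolve(mm)  # fatal if the core site is absent
    hm.annotate_carriers(core_index)
    return hm, mm, report


def write_tabular(hm: HaplotypeMatrix, mm: MarkerMap, path) -> None:
    """One row per chromosome: sample_id, phase, then one column per marker."""
    df = pd.DataFrame(hm.entries, columns=mm.marker_ids.tolist())
    df.insert(0, "phase", hm.phase_index)
    df.insert(0, "sample_id", [s for s in hm.sample_ids for _ in (0, 1)])
    df.to_csv(path, sep="\t", index=False)


def read_tabular(path, mm: MarkerMap) -> HaplotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    ids = mm.marker_ids.tolist()
    entries = df[ids].to_numpy(dtype=np.int8)
    samples = df["sample_id"].tolist()[::2]
    return HaplotypeMatrix(entries, samples)


# ---------------------------------------------------------------------------
# QC: Hardy-Weinberg exact test and marker filtering
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (Levene/Haldane conditional distribution). Returns p in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = n_Aa + 2 * n_aa  # minor-allele count (label-symmetric)
    n_a = min(n_a, 2 * n - n_a)

    # attainable het counts share the parity of the rarer allele count
    hets = np.arange(n_a % 2, n_a + 1, 2)
    homr = (n_a - hets) // 2
    homc = n - hets - homr
    valid = homc >= 0
    hets, homr, homc = hets[valid], homr[valid], homc[valid]
    # log P(het | n, n_a) up to the shared normalizer
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = n_Aa
    p_obs = p[hets == obs]
    if len(p_obs) == 0:  # observed het count has wrong parity => impossible
        raise ValueError("inconsistent genotype counts")
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


@dataclass
class FilterReport:
    n_input: int
    n_call_rate: int
    n_hwe: int
    n_r2: int
    n_impute_acc: int
    n_retained: int
    n_imputed_entries: int


def filter_markers(
    hm: HaplotypeMatrix,
    mm: MarkerMap,
    core: CoreSite | None = None,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.01,
    r2_min: float = 0.95,
    impute_acc_min: float = 0.98,
) -> tuple[HaplotypeMatrix, MarkerMap, FilterReport]:
    """Marker QC: call rate >= 95% and HWE exact p >= 0.01 by default.

    HWE is evaluated on non-carrier samples only (the carrier set is
    ascertained). Optional per-marker ``r2`` / ``impute_acc`` columns in the
    map, when present, are filtered at their thresholds; absent columns are
    skipped. Residual missingness in surviving markers is imputed to the
    per-site major allele (deterministic), so the returned matrix is
    complete. The core site, when given, is always retained.
    """
    ent = hm.entries
    n_chrom, n_sites = ent.shape
    observed = ent != MISSING
    call_rate = observed.mean(axis=0)
    fail_cr = call_rate < call_rate_min

    if core is not None:
        core_index = core.resolve(mm)
        hwe_rows = hm.noncarrier_rows(core_index)
    else:
        core_index = None
        hwe_rows = np.arange(n_chrom)
    geno = ent[hwe_rows].reshape(-1, 2, n_sites)
    fail_hwe = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        g = geno[:, :, j]
        ok = (g != MISSING).all(axis=1)
        g = g[ok]
        if len(g) == 0:
            continue
        cnt = g.sum(axis=1)
        p = hwe_exact_test(
            int((cnt == 0).sum()), int((cnt == 1).sum()), int((cnt == 2).sum())
        )
        fail_hwe[j] = p < hwe_alpha

    fail_r2 = np.zeros(n_sites, dtype=bool)
    if "r2" in mm.df.columns and mm.df["r2"].notna().any():
        r2 = mm.df["r2"].to_numpy(dtype=float)
        fail_r2 = np.nan_to_num(r2, nan=1.0) < r2_min
    fail_acc = np.zeros(n_sites, dtype=bool)
    if "impute_acc" in mm.df.columns and mm.df["impute_acc"].notna().any():
        acc = mm.df["impute_acc"].to_numpy(dtype=float)
        fail_acc = np.nan_to_num(acc, nan=1.0) < impute_acc_min

    fail_any = fail_cr | fail_hwe | fail_r2 | fail_acc
    if core_index is not None:
        fail_any[core_index] = False
    keep = np.flatnonzero(~fail_any)
    if len(keep) == 0:
        raise ValueError(
            f"all {n_sites} markers removed by QC "
            f"(call-rate {int(fail_cr.sum())}, HWE {int(fail_hwe.sum())})"
        )

    ent2 = ent[:, keep].copy()
    n_imputed = int((ent2 == MISSING).sum())
    if n_imputed:
        # impute residual missing calls to the per-site major allele
        freq = np.where(
            (ent2 != MISSING).any(axis=0),
            (ent2 == 1).sum(axis=0) / np.maximum((ent2 != MISSING).sum(axis=0), 1),
            0.0,
        )
        major = (freq > 0.5).astype(np.int8)
        miss_r, miss_c = np.nonzero(ent2 == MISSING)
        ent2[miss_r, miss_c] = major[miss_c]
        logger.info("imputed %d residual missing calls to major allele", n_imputed)

    report = FilterReport(
        n_input=n_sites,
        n_call_rate=int(fail_cr.sum()),
        n_hwe=int(fail_hwe.sum()),
        n_r2=int(fail_r2.sum()),
        n_impute_acc=int(fail_acc.sum()),
        n_retained=len(keep),
        n_imputed_entries=n_imputed,
    )
    hm2 = HaplotypeMatrix(
        ent2, list(hm.sample_ids), list(hm.carrier_status), list(hm.affection)
    )
    return hm2, mm.subset(keep), report
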