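"""Allele-frequency arithmetic and two-population comparison.

Covers the carrier-frequency bookkeeping used when contrasting a local
founder-allele frequency against reference panels: frequency from counts,
fold enrichment between two populations, and the two-sided Fisher exact
test on the 2x2 allele-count table.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["FreqRow", "allele_frequency", "fold_enrichment", "fisher_exact"]


@dataclass
class FreqRow:
    label: str
    derived_count: int
    total_alleles: int

    def __post_init__(self):
        if self.total_alleles < 1:
            raise ValueError("total_alleles must be >= 1")
        if not (0 <= self.derived_count <= self.total_alleles):
            raise ValueError("derived_count must lie in [0, total_alleles]")

    @property
    def maf(self) -> float:
        return self.derived_count / self.total_alleles


def allele_frequency(derived_count: int, total_alleles: int) -> float:
    """Allele frequency = count / total; bounds-checked."""
    return FreqRow("", derived_count, total_alleles).maf


def fold_enrichment(
    f1: FreqRow, f2: FreqRow, continuity_correction: bool = False
) -> float:
    """Frequency ratio f1/f2 between two populations.

    A zero denominator raises unless ``continuity_correction`` adds 0.5 to
    both derived counts (flagged, never the default).
    """
    if continuity_correction:
        return ((f1.derived_count + 0.5) / (f1.total_alleles + 1)) / (
            (f2.derived_count + 0.5) / (f2.total_alleles + 1)
        )
    if f2.maf == 0:
        raise ValueError(
            "reference frequency is 0; pass continuity_correction=True for a "
            "corrected ratio"
        )
    return f1.maf / f2.maf


def fisher_exact(c1: int, n1: int, c2: int, n2: int, mid_p: bool = False) -> float:
    """Two-sided Fisher exact test on the 2x2 table
    [[c1, n1-c1], [c2, n2-c2]] (point-probability summation).

    ``mid_p`` halves the observed table's point probability (mid-p variant).
    Degenerate margins give p = 1.
    """
    if not (0 <= c1 <= n1) or not (0 <= c2 <= n2):
        raise ValueError("counts must lie within their totals")
    table = [[c1, n1 - c1], [c2, n2 - c2]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if mid_p:
        k, M, nn, N = c1, n1 + n2, c1 + c2, n1
        p -= 0.5 * float(stats.hypergeom.pmf(k, M, nn, N))
    return min(p, 1.0)
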