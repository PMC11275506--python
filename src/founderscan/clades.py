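"""Haplotype clade partitioning: TN93 distances, neighbor joining, and
signature-SNP clade assignment.

Haplotypes are rendered as nucleotide strings through the marker map's
ancestral/derived bases before any distance computation. The Tamura-Nei
1993 model distinguishes the two transition types (A<->G within purines,
C<->T within pyrimidines) from transversions and allows unequal base
frequencies; its maximum-likelihood pairwise distance has the closed form

    d = -k1 ln(w1) - k2 ln(w2) - k3 ln(w3)

with w1 = 1 - pR*P1/(2 pA pG) - Q/(2 pR), w2 analogous for pyrimidines,
w3 = 1 - Q/(2 pR pY), where P1, P2, Q are the observed proportions of
purine transitions, pyrimidine transitions and transversions, and the k's
are base-frequency weights. Trees are built by classical neighbor joining
with deterministic tie-breaking; the clade partition itself is read off a
small set of signature SNPs, which is what the tree substitutes for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix, MarkerMap

__all__ = [
    "tn93_distance",
    "distance_matrix",
    "neighbor_joining",
    "assign_clades",
    "haplotype_strings",
    "CladeAssignment",
    "DEFAULT_SIGNATURE_MARKERS",
    "DEFAULT_CLADE_PATTERNS",
]

# the five clade-defining SNPs spanning 40.1-40.3 Mb, and the three observed
# clade patterns (bracket positions carry two clade-internal alleles)
DEFAULT_SIGNATURE_MARKERS = [
    "rs2638245",
    "rs10878199",
    "rs2638271",
    "rs2708438",
    "rs1388587",
]
DEFAULT_CLADE_PATTERNS = {
    "clade1": "TTCA[G/C]",
    "clade2": "CTG[A/G]G",
    "clade3": "TT[C/G]GC",
}

_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def tn93_distance(
    seq_a: str,
    seq_b: str,
    saturation_ceiling: float = 10.0,
) -> tuple[float, bool]:
    """TN93 distance between two equal-length nucleotide strings.

    Sites where either sequence carries a symbol outside A/C/G/T are
    pairwise-deleted. Base frequencies are pooled over both sequences.
    Saturated pairs (any logarithm argument <= 0) are reported at
    ``saturation_ceiling`` with the flag set.

    Returns ``(distance, saturated)``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    acgt = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    valid = np.isin(a, acgt) & np.isin(b, acgt)
    a, b = a[valid], b[valid]
    n = len(a)
    if n == 0:
        raise ValueError("no comparable A/C/G/T sites")

    pooled = np.concatenate([a, b])
    freqs = {base: float((pooled == base.encode()).mean()) for base in _BASES}
    pA, pC, pG, pT = (freqs[x] for x in _BASES)
    pR, pY = pA + pG, pC + pT

    diff = a != b
    P1 = P2 = Q = 0
    for x, y in zip(a[diff], b[diff]):
        pair = {x.decode(), y.decode()}
        if pair == {"A", "G"}:
            P1 += 1
        elif pair == {"C", "T"}:
            P2 += 1
        else:
            Q += 1
    P1, P2, Q = P1 / n, P2 / n, Q / n
    if P1 == P2 == Q == 0:
        return 0.0, False

    try:
        d = 0.0
        # vanishing-frequency terms drop out (their coefficients -> 0), but
        # an observed change of that type with zero frequency is saturation
        if pA * pG > 0 and pR > 0:
            w1 = 1 - pR * P1 / (2 * pA * pG) - Q / (2 * pR)
            if w1 <= 0:
                raise ValueError
            d += -(2 * pA * pG / pR) * math.log(w1)
        elif P1 > 0:
            raise ValueError
        if pC * pT > 0 and pY > 0:
            w2 = 1 - pY * P2 / (2 * pC * pT) - Q / (2 * pY)
            if w2 <= 0:
                raise ValueError
            d += -(2 * pC * pT / pY) * math.log(w2)
        elif P2 > 0:
            raise ValueError
        if pR * pY > 0:
            w3 = 1 - Q / (2 * pR * pY)
            if w3 <= 0:
                raise ValueError
            coef = pR * pY
            if pR > 0:
                coef -= pA * pG * pY / pR
            if pY > 0:
                coef -= pC * pT * pR / pY
            d += -2 * coef * math.log(w3)
        elif Q > 0:
            raise ValueError
        return float(d), False
    except ValueError:
        return float(saturation_ceiling), True


def haplotype_strings(
    hm: HaplotypeMatrix, mm: MarkerMap, site_indices: np.ndarray | None = None
) -> list[str]:
    """Render 0/1 haplotypes as nucleotide strings via the marker map."""
    idx = (
        np.arange(hm.n_sites) if site_indices is None else np.asarray(site_indices)
    )
    anc = mm.df["ancestral"].to_numpy()[idx]
    der = mm.df["derived"].to_numpy()[idx]
    out = []
    for row in hm.entries[:, idx]:
        out.append("".join(d if v == 1 else a for v, a, d in zip(row, anc, der)))
    return out


def distance_matrix(
    seqs: list[str],
    labels: list[str] | None = None,
    saturation_ceiling: float = 10.0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Symmetric TN93 distance matrix over sequences; saturated pairs listed."""
    n = len(seqs)
    labels = labels or [f"h{i}" for i in range(n)]
    d = np.zeros((n, n))
    flagged = []
    for i in range(n):
        for j in range(i + 1, n):
            dij, sat = tn93_distance(seqs[i], seqs[j], saturation_ceiling)
            d[i, j] = d[j, i] = dij
            if sat:
                flagged.append((labels[i], labels[j]))
    return pd.DataFrame(d, index=labels, columns=labels), flagged


@dataclass
class _Node:
    label: str | None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{child.newick()}:{length:.10g}" for child, length in self.children
        )
        return f"({inner})"


def neighbor_joining(dm: pd.DataFrame) -> str:
    """Classical neighbor joining; returns an unrooted tree in newick.

    Ties in the Q criterion break deterministically on the (row, column)
    index pair in label order. Negative branch lengths are clamped to zero
    with the deficit moved onto the sibling branch, preserving the path
    length between the joined pair.
    """
    labels = list(dm.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dm.to_numpy(dtype=float).copy()
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes: list[_Node] = [_Node(lbl) for lbl in labels]
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: first (i, j) in index order at the minimum
        flat = np.argmin(q)
        i_, j_ = divmod(int(flat), m)
        if i_ > j_:
            i_, j_ = j_, i_
        li = (sub[i_, j_] + (r[i_] - r[j_]) / (m - 2)) / 2
        lj = sub[i_, j_] - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        a, b = active[i_], active[j_]
        new = _Node(None, [(nodes[a], li), (nodes[b], lj)])
        # distances from the new node to every other active node
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        for t in active:
            if t in (a, b):
                continue
            d[k, t] = d[t, k] = (d[a, t] + d[b, t] - d[a, b]) / 2
        nodes.append(new)
        active = [t for t in active if t not in (a, b)] + [k]

    # terminal three-taxon join: branch lengths from the three-point formulas
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(
        None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)]
    )
    return root.newick() + ";"


@dataclass
class CladeAssignment:
    signature_markers: list[str]
    patterns: dict[str, str]
    per_haplotype: pd.DataFrame  # chrom_id, allele_string, clade
    counts: dict[str, int]
    frequencies: dict[str, float]
    unassigned: list[str]  # distinct allele strings matching no clade

    def summary(self) -> str:
        lines = ["Clade assignment", "=" * 46]
        lines.append("signature SNPs: " + ", ".join(self.signature_markers))
        for name, pat in self.patterns.items():
            n = self.counts.get(name, 0)
            f = self.frequencies.get(name, 0.0)
            lines.append(f"  {name:8s} {pat:12s} n = {n:4d}  freq = {f:.2f}")
        if self.unassigned:
            lines.append(f"  unassigned patterns: {len(self.unassigned)}")
        return "\n".join(lines)


def _pattern_tokens(pattern: str) -> list[set[str]]:
    tokens, i = [], 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            tokens.append(set(pattern[i + 1 : j].replace("/", "")))
            i = j + 1
        else:
            tokens.append({pattern[i]})
            i += 1
    return tokens


def assign_clades(
    hm: HaplotypeMatrix,
    mm: MarkerMap,
    signature_markers: list[str] | None = None,
    patterns: dict[str, str] | None = None,
) -> CladeAssignment:
    """Assign each haplotype to a clade by its allele string over the
    signature SNPs; bracketed pattern positions accept either allele.

    Frequencies are over assigned haplotypes and sum to 1; haplotypes whose
    strings match no pattern go to the unassigned bucket.
    """
    signature_markers = signature_markers or DEFAULT_SIGNATURE_MARKERS
    patterns = patterns or DEFAULT_CLADE_PATTERNS
    idx = np.array([mm.index_of(m) for m in signature_markers])  # fatal if absent
    strings = haplotype_strings(hm, mm, idx)
    tokenized = {name: _pattern_tokens(p) for name, p in patterns.items()}
    for name, toks in tokenized.items():
        if len(toks) != len(signature_markers):
            raise ValueError(
                f"pattern {name!r} has {len(toks)} positions, expected "
                f"{len(signature_markers)}"
            )

    clade_of = []
    for s in strings:
        hit = None
        for name, toks in tokenized.items():
            if all(ch in tok for ch, tok in zip(s, toks)):
                hit = name
                break
        clade_of.append(hit)

    per_hap = pd.DataFrame(
        {"chrom_id": hm.chrom_ids, "allele_string": strings, "clade": clade_of}
    )
    assigned = per_hap[per_hap["clade"].notna()]
    counts = assigned["clade"].value_counts().to_dict()
    total = int(sum(counts.values()))
    freqs = {k: v / total for k, v in counts.items()} if total else {}
    unassigned = sorted(
        per_hap.loc[per_hap["clade"].isna(), "allele_string"].unique()
    )
    return CladeAssignment(
        signature_markers=list(signature_markers),
        patterns=dict(patterns),
        per_haplotype=per_hap,
        counts={k: int(v) for k, v in counts.items()},
        frequencies=freqs,
        unassigned=list(unassigned),
    )
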