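"""TN93 distances, neighbor joining, and signature-SNP clade assignment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderscan.clades import (
    DEFAULT_CLADE_PATTERNS,
    DEFAULT_SIGNATURE_MARKERS,
    assign_clades,
    distance_matrix,
    neighbor_joining,
    tn93_distance,
)
from founderscan.hapio import HaplotypeMatrix, MarkerMap


def tn93_oracle(a, b):
    """Independent evaluation of the TN93 closed form (scalar arithmetic,
    written separately from the library's vectorized path)."""
    pairs = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(pairs)
    pooled = "".join(x + y for x, y in pairs)
    pi = {base: pooled.count(base) / (2 * n) for base in "ACGT"}
    P1 = sum(1 for x, y in pairs if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in pairs if {x, y} == {"C", "T"}) / n
    Q = (
        sum(1 for x, y in pairs if x != y and {x, y} not in ({"A", "G"}, {"C", "T"}))
        / n
    )
    pR, pY = pi["A"] + pi["G"], pi["C"] + pi["T"]
    k1 = 2 * pi["A"] * pi["G"] / pR
    k2 = 2 * pi["C"] * pi["T"] / pY
    k3 = 2 * (pR * pY - pi["A"] * pi["G"] * pY / pR - pi["C"] * pi["T"] * pR / pY)
    w1 = 1 - P1 / k1 - Q / (2 * pR)
    w2 = 1 - P2 / k2 - Q / (2 * pY)
    w3 = 1 - Q / (2 * pR * pY)
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def random_seq(rng, n=200):
    return "".join(rng.choice(list("ACGT"), n))


def mutate(rng, seq, n_changes):
    s = list(seq)
    for i in rng.choice(len(s), n_changes, replace=False):
        s[i] = "ACGT"[(("ACGT".index(s[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


class TestTn93Distance:
    def test_identical_sequences_zero(self):
        assert tn93_distance("ACGTACGT", "ACGTACGT") == (0.0, False)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            a = random_seq(rng)
            b = mutate(rng, a, int(rng.integers(1, 40)))
            d, sat = tn93_distance(a, b)
            if sat:
                continue
            assert d == pytest.approx(tn93_oracle(a, b), abs=1e-10)
            checked += 1
        assert checked > 150

    def test_reference_values(self):
        """Frozen cross-package reference: ape::dist.dna(model="TN93") on the
        same sequences gives 0.0254591 / 0.0798507 / 0.2337554 (pairwise
        deletion); agreement to ~1e-4 (frequency-estimator detail)."""
        rng = np.random.default_rng(42)
        base = rng.choice(list("ACGT"), 200)
        s0 = "".join(base)
        expected = {5: 0.0254591, 15: 0.0798507, 40: 0.2337554}
        for nmut, ref in expected.items():
            sj = mutate(rng, s0, nmut)
            d, sat = tn93_distance(s0, sj)
            assert not sat
            assert d == pytest.approx(ref, abs=2e-4)

    def test_at_least_raw_mismatch_proportion(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = random_seq(rng, 300)
            b = mutate(rng, a, int(rng.integers(1, 60)))
            d, sat = tn93_distance(a, b)
            raw = sum(x != y for x, y in zip(a, b)) / len(a)
            if not sat:
                assert d >= raw - 1e-12

    def test_saturation_ceiling(self):
        d, sat = tn93_distance("A" * 50, "G" * 50, saturation_ceiling=9.0)
        assert sat and d == 9.0

    def test_pairwise_deletion(self):
        d, _ = tn93_distance("ACGTN", "ACGTA")
        assert d == 0.0

    def test_symmetry_matrix(self):
        rng = np.random.default_rng(5)
        seqs = [random_seq(rng, 80) for _ in range(6)]
        dm, flagged = distance_matrix(seqs)
        arr = dm.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0)


def newick_topology(newick, labels):
    """Leaf bipartitions of an unrooted newick tree via dendropy."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    t.encode_bipartitions()
    return {
        frozenset(taxon.label for taxon in b.leafset_taxa(t.taxon_namespace))
        for b in t.bipartition_encoding
        if 1 < len(b.leafset_taxa(t.taxon_namespace)) < len(labels) - 1
    }


def rf_distance(nwk1, nwk2, labels):
    """Unrooted Robinson-Foulds distance between two newick strings."""
    import dendropy

    tns = dendropy.TaxonNamespace(labels)
    trees = []
    for nwk in (nwk1, nwk2):
        t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
        t.is_rooted = False
        t.update_bipartitions()
        trees.append(t)
    return dendropy.calculate.treecompare.symmetric_difference(*trees)


def additive_distances_from_random_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths -> leaf distance
    matrix (path metric), computed via dendropy."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=__import__("random").Random(int(rng.integers(1e9))),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    d = np.zeros((n_taxa, n_taxa))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i < j:
                d[i, j] = d[j, i] = pdm.patristic_distance(ti, tj)
    return pd.DataFrame(d, index=labels, columns=labels), tree


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        nwk = neighbor_joining(d)
        # three-point formulas: la=1, lb=2, lc=3
        assert "a:1" in nwk and "b:2" in nwk and "c:3" in nwk

    def test_four_taxon_additive_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)); exact additive distances
        d = pd.DataFrame(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0 + 7, 0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
        )
        d.iloc[3, 2] = 7
        d.iloc[2, 3] = 7
        nwk = neighbor_joining(d)
        topo = newick_topology(nwk, list("abcd"))
        assert frozenset({"a", "b"}) in topo or frozenset({"c", "d"}) in topo

    def test_fewer_than_three_taxa(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            neighbor_joining(d)

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_random_additive_metric_recovery(self, n_taxa, rng):
        """NJ reconstructs the generating topology of any additive metric."""
        dm, tree = additive_distances_from_random_tree(rng, n_taxa)
        nwk = neighbor_joining(dm)
        labels = [f"t{i}" for i in range(n_taxa)]
        assert rf_distance(nwk, tree.as_string(schema="newick"), labels) == 0

    def test_agrees_with_skbio_topology(self, rng):
        """Independent cross-check against scikit-bio's NJ."""
        dm, _ = additive_distances_from_random_tree(rng, 7)
        nwk = neighbor_joining(dm)
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        sk = skbio_nj(SkbioDM(dm.to_numpy(), ids=list(dm.index)))
        assert rf_distance(nwk, str(sk).strip(), list(dm.index)) == 0


def clade_panel(counts=(41, 73, 54)):
    """Panel whose signature-SNP strings realize the three clade patterns."""
    strings = (
        ["TTCAG"] * (counts[0] // 2)
        + ["TTCAC"] * (counts[0] - counts[0] // 2)
        + ["CTGAG"] * (counts[1] // 2)
        + ["CTGGG"] * (counts[1] - counts[1] // 2)
        + ["TTCGC"] * (counts[2] // 2)
        + ["TTGGC"] * (counts[2] - counts[2] // 2)
    )
    anc = list("TTCAG")
    der = list("CAGGC")
    ent = np.array(
        [[0 if ch == a else 1 for ch, a in zip(s, anc)] for s in strings],
        dtype=np.int8,
    )
    mm = MarkerMap(
        pd.DataFrame(
            dict(
                chrom="12",
                pos_bp=[40_100_000, 40_150_000, 40_200_000, 40_250_000, 40_300_000],
                marker_id=DEFAULT_SIGNATURE_MARKERS,
                ancestral=anc,
                derived=der,
            )
        )
    )
    return HaplotypeMatrix.from_haplotypes(ent), mm


class TestAssignClades:
    def test_reference_counts_and_frequencies(self):
        hm, mm = clade_panel()
        ca = assign_clades(hm, mm)
        assert ca.counts == {"clade1": 41, "clade2": 73, "clade3": 54}
        assert round(ca.frequencies["clade1"], 2) == 0.24
        assert round(ca.frequencies["clade2"], 2) == 0.43
        assert round(ca.frequencies["clade3"], 2) == 0.32

    def test_frequencies_sum_to_one(self):
        hm, mm = clade_panel((10, 20, 30))
        ca = assign_clades(hm, mm)
        assert sum(ca.frequencies.values()) == pytest.approx(1.0)

    def test_unmatched_pattern_unassigned(self):
        hm, mm = clade_panel((4, 4, 4))
        hm.entries[0] = [1, 1, 1, 1, 1]  # CAGGC: matches no clade pattern
        ca = assign_clades(hm, mm)
        assert "CAGGC" in ca.unassigned

    def test_identical_haplotypes_single_clade(self):
        hm, mm = clade_panel((6, 0, 0))
        ca = assign_clades(hm, mm)
        assert ca.frequencies == {"clade1": 1.0}

    def test_haplotype_order_invariance(self, rng):
        hm, mm = clade_panel()
        perm = rng.permutation(hm.n_chromosomes)
        hm2 = HaplotypeMatrix.from_haplotypes(hm.entries[perm])
        assert assign_clades(hm2, mm).counts == assign_clades(hm, mm).counts

    def test_missing_signature_marker_fatal(self):
        hm, mm = clade_panel()
        with pytest.raises(KeyError):
            assign_clades(hm, mm, signature_markers=["rs_missing"] * 5,
                          patterns={"c": "AAAAA"})
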