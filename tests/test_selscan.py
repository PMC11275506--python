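"""EHH decay, iHH integration, and iHS standardization."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderscan.hapio import HaplotypeMatrix, MarkerMap
from founderscan.selscan import (
    EhhCurve,
    IhsScan,
    ehh,
    integrate_ihh,
    standardize_ihs,
    unstandardized_ihs,
)


def brute_force_ehh(ent, core, cls, direction, trunc=0.05):
    """Materialize every extended haplotype string and count identical
    pairs — the independent reference for ehh()."""
    rows = np.flatnonzero(ent[:, core] == cls)
    n = len(rows)
    sites, curve = [core], [1.0]
    j = core
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= ent.shape[1]:
            break
        j = j_next
        lo, hi = min(core, j), max(core, j)
        counts = Counter(tuple(ent[r, lo : hi + 1]) for r in rows)
        e = sum(v * (v - 1) for v in counts.values()) / (n * (n - 1))
        sites.append(j)
        curve.append(e)
        if e < trunc:
            break
    return sites, curve


class TestEhh:
    def test_equals_one_at_core(self):
        ent = np.array([[0, 1, 0], [0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        hm = HaplotypeMatrix.from_haplotypes(ent)
        c = ehh(hm, 1, 1, +1, max_gap_bp=None)
        assert c.ehh[0] == 1.0

    def test_two_equal_groups_give_one_third(self):
        # 4 chromosomes split {2,2} one site right of the core
        ent = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1]], dtype=np.int8
        )
        hm = HaplotypeMatrix.from_haplotypes(ent)
        c = ehh(hm, 0, 1, +1, max_gap_bp=None)
        assert c.ehh[1] == pytest.approx(1 / 3)

    def test_all_distinct_stops_at_zero(self):
        ent = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1]], dtype=np.int8)
        # 3 chromosomes, all distinct over the first two extension sites
        hm = HaplotypeMatrix.from_haplotypes(ent)
        c = ehh(hm, 0, 1, +1, max_gap_bp=None)
        assert c.ehh[-1] < 0.05 and c.truncation == "threshold"

    def test_small_class_unscorable(self):
        ent = np.zeros((4, 3), dtype=np.int8)
        ent[0, 1] = 1
        hm = HaplotypeMatrix.from_haplotypes(ent)
        with pytest.raises(ValueError, match=">= 2"):
            ehh(hm, 1, 1, +1)

    def test_gap_truncation(self):
        ent = np.ones((4, 3), dtype=np.int8)
        hm = HaplotypeMatrix.from_haplotypes(ent)
        pos = np.array([0, 1000, 500_000])
        c = ehh(hm, 0, 1, +1, max_gap_bp=10_000, pos_bp=pos)
        assert c.truncation == "gap" and list(c.site_indices) == [0, 1]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(4, 30),
        m=st.integers(5, 40),
    )
    def test_matches_brute_force(self, seed, n, m):
        rng = np.random.default_rng(seed)
        ent = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        hm = HaplotypeMatrix.from_haplotypes(ent)
        core = int(rng.integers(0, m))
        for cls in (0, 1):
            if (ent[:, core] == cls).sum() < 2:
                continue
            for direction in (-1, 1):
                c = ehh(hm, core, cls, direction, max_gap_bp=None)
                sites, curve = brute_force_ehh(ent, core, cls, direction)
                assert list(c.site_indices) == sites
                np.testing.assert_allclose(c.ehh, curve, atol=1e-12)

    def test_monotone_nonincreasing(self, rng):
        ent = rng.integers(0, 2, size=(30, 50)).astype(np.int8)
        hm = HaplotypeMatrix.from_haplotypes(ent)
        for core in (0, 25, 49):
            for cls in (0, 1):
                if (ent[:, core] == cls).sum() < 2:
                    continue
                c = ehh(hm, core, cls, +1 if core < 25 else -1, max_gap_bp=None)
                assert np.all(np.diff(c.ehh) <= 1e-12)

    def test_relabeling_invariance(self, rng):
        ent = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
        perm = rng.permutation(20)
        a = ehh(HaplotypeMatrix.from_haplotypes(ent), 15, 0, -1, max_gap_bp=None)
        b = ehh(
            HaplotypeMatrix.from_haplotypes(ent[perm]), 15, 0, -1, max_gap_bp=None
        )
        np.testing.assert_allclose(a.ehh, b.ehh)


def curve(ehh_vals, pos, truncation="chromosome-end"):
    return EhhCurve(
        core_index=0,
        allele_class=1,
        direction=+1,
        site_indices=np.arange(len(ehh_vals)),
        pos_bp=np.asarray(pos),
        ehh=np.asarray(ehh_vals, dtype=float),
        truncation=truncation,
    )


class TestIntegrateIhh:
    def test_unit_rectangle(self):
        c = curve([1.0, 1.0], [0, 1_000_000])
        assert integrate_ihh(c) == pytest.approx(1.0)

    def test_linear_decay_to_threshold(self):
        c = curve([1.0, 0.05], [0, 1_000_000])
        assert integrate_ihh(c) == pytest.approx((1 + 0.05) / 2)

    def test_subthreshold_tail_interpolated(self):
        # crossing 0.05 halfway through the last (zero-valued) segment:
        # area = full trapezoid of [1, .05] over the interpolated span
        c = curve([1.0, 0.6, 0.0], [0, 1_000_000, 2_000_000], "threshold")
        # crossing point of 0.05 between 0.6 and 0.0
        frac = (0.6 - 0.05) / 0.6
        expected = (1 + 0.6) / 2 * 1.0 + (0.6 + 0.05) / 2 * frac
        assert integrate_ihh(c) == pytest.approx(expected)

    def test_symmetric_curves_double(self):
        left = curve([1.0, 0.4, 0.1], [0, -500_000, -1_000_000])
        right = curve([1.0, 0.4, 0.1], [0, 500_000, 1_000_000])
        assert integrate_ihh(left) == pytest.approx(integrate_ihh(right))


class TestUnstandardizedIhs:
    def test_equal_areas_zero(self):
        assert unstandardized_ihs(2.0, 2.0) == 0.0

    def test_ln2(self):
        assert unstandardized_ihs(2.0, 1.0) == pytest.approx(np.log(2))

    def test_long_derived_negative(self):
        assert unstandardized_ihs(1.0, 3.0) < 0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            unstandardized_ihs(0.0, 1.0)


def table_from(uihs, p=None):
    uihs = np.asarray(uihs, dtype=float)
    return pd.DataFrame(
        dict(
            marker_id=[f"m{i}" for i in range(len(uihs))],
            pos_bp=np.arange(len(uihs)) * 1000 + 1,
            p=p if p is not None else np.full(len(uihs), 0.5),
            iHHA=np.ones(len(uihs)),
            iHHD=np.ones(len(uihs)),
            uihs=uihs,
            scorable=np.isfinite(uihs),
        )
    )


class TestStandardizeIhs:
    def test_two_point_bin_exact(self):
        out = standardize_ihs(table_from([-1.0, 1.0]), n_bins=1, min_bin=2)
        np.testing.assert_allclose(sorted(out["ihs"]), [-1.0, 1.0])

    def test_degenerate_bin_flagged(self):
        out = standardize_ihs(table_from([0.7, 0.7, 0.7]), n_bins=1, min_bin=2)
        assert not out["scorable"].any()
        assert out["ihs"].isna().all()

    def test_per_bin_mean_zero_var_one(self, rng):
        p = rng.uniform(0.02, 0.98, 600)
        uihs = rng.normal(0.3 * p, 1.0)
        out = standardize_ihs(table_from(uihs, p), n_bins=50, min_bin=20)
        for _, grp in out[out["scorable"]].groupby("freq_bin"):
            assert abs(grp["ihs"].mean()) < 1e-6
            assert abs(np.var(grp["ihs"]) - 1.0) < 1e-6

    def test_bins_merge_to_min_size(self, rng):
        p = rng.uniform(0.02, 0.98, 120)
        out = standardize_ihs(table_from(rng.normal(size=120), p), min_bin=20)
        sizes = out[out["scorable"]].groupby("freq_bin").size()
        assert (sizes >= 20).all()


class TestIhsScanInvariants:
    def test_sign_flip_under_allele_swap(self, rng):
        """Recoding ancestral<->derived at the core negates uihs exactly."""
        ent = rng.integers(0, 2, size=(40, 60)).astype(np.int8)
        mm = MarkerMap(
            pd.DataFrame(
                dict(
                    chrom="12",
                    pos_bp=np.arange(60) * 5000 + 1,
                    marker_id=[f"m{i}" for i in range(60)],
                    ancestral=["A"] * 60,
                    derived=["G"] * 60,
                )
            )
        )
        hm = HaplotypeMatrix.from_haplotypes(ent)
        res = IhsScan(hm, mm, min_bin=5).fit()
        ent2 = ent.copy()
        ent2[:, 30] ^= 1
        res2 = IhsScan(HaplotypeMatrix.from_haplotypes(ent2), mm, min_bin=5).fit()
        u1 = res.table.loc[30, "uihs"]
        u2 = res2.table.loc[30, "uihs"]
        assert np.isfinite(u1)
        assert u2 == pytest.approx(-u1, rel=1e-12)

    def test_chromosome_order_invariance(self, rng):
        ent = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
        mm = MarkerMap(
            pd.DataFrame(
                dict(
                    chrom="12",
                    pos_bp=np.arange(40) * 5000 + 1,
                    marker_id=[f"m{i}" for i in range(40)],
                    ancestral=["A"] * 40,
                    derived=["G"] * 40,
                )
            )
        )
        a = IhsScan(HaplotypeMatrix.from_haplotypes(ent), mm, min_bin=5).fit()
        perm = rng.permutation(30)
        b = IhsScan(HaplotypeMatrix.from_haplotypes(ent[perm]), mm, min_bin=5).fit()
        pd.testing.assert_frame_equal(a.table, b.table)
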