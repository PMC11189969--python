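import itertools

import numpy as np
import pytest
from scipy import stats as sps

import footmorph as fm


@pytest.fixture(scope="module")
def two_lobed():
    return fm.make_pressure_map(seed=0)


def wilcoxon_enumeration_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    ranks = sps.rankdata(np.abs(diffs))
    observed = ranks[np.asarray(diffs) > 0].sum()
    n = len(diffs)
    total = ranks.sum()
    stat_obs = min(observed, total - observed)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, total - w_plus) <= stat_obs:
            count += 1
    return count / 2 ** n


class TestPartition:
    def test_lobes_fall_in_expected_regions(self, two_lobed):
        masks = fm.partition_regions(two_lobed, fm.RegionScheme.seven())
        peak_idx = np.unravel_index(np.argmax(two_lobed.values), two_lobed.values.shape)
        heel_mask = masks["medial heel"] | masks["lateral heel"]
        assert heel_mask[peak_idx]
        fore = (masks["medial forefoot"] | masks["middle forefoot"]
                | masks["lateral forefoot"] | masks["hallux"])
        fore_vals = np.where(fore, two_lobed.values, 0.0)
        fore_idx = np.unravel_index(np.argmax(fore_vals), fore_vals.shape)
        # the forefoot lobe centre must land in the forefoot regions
        assert fore[fore_idx]
        assert two_lobed.values[fore_idx] > 100.0

    def test_masks_disjoint_and_cover_footprint(self, two_lobed):
        for scheme in (fm.RegionScheme.seven(), fm.RegionScheme.eight()):
            masks = fm.partition_regions(two_lobed, scheme)
            total = sum(m.astype(int) for m in masks.values())
            fp = two_lobed.footprint()
            assert np.all(total[fp] == 1)
            assert np.all(total[~fp] == 0)

    def test_uniform_rectangle_band_areas(self):
        # uniform unit pressure on a rectangular footprint: region cell counts
        # must match the band-fraction products within one cell row/column
        x = np.arange(-30.0, 31.0, 5.0)
        y = np.arange(0.0, 251.0, 5.0)
        values = np.ones((len(y), len(x)))
        pmap = fm.PressureMap(x, y, values,
                              heel_point=np.array([0.0, 0.0]),
                              toe_direction=np.array([0.0, 1.0]))
        scheme = fm.RegionScheme.seven()
        masks = fm.partition_regions(pmap, scheme)
        total = values.sum()
        ny, nx = values.shape
        row = nx  # one grid row of cells
        heel = masks["medial heel"].sum() + masks["lateral heel"].sum()
        assert abs(heel - 0.30 * total) <= row
        assert abs(masks["midfoot"].sum() - 0.30 * total) <= row
        fore_and_toes = sum(masks[k].sum() for k in
                            ("medial forefoot", "middle forefoot",
                             "lateral forefoot", "hallux"))
        assert abs(fore_and_toes - 0.40 * total) <= row
        # hallux: medial third of the 15% toe band
        assert abs(masks["hallux"].sum() - 0.15 * total / 3) <= 0.15 * ny + row

    def test_seven_vs_eight_differ_only_in_midfoot(self, two_lobed):
        seven = fm.partition_regions(two_lobed, fm.RegionScheme.seven())
        eight = fm.partition_regions(two_lobed, fm.RegionScheme.eight())
        np.testing.assert_array_equal(
            seven["midfoot"], eight["medial midfoot"] | eight["lateral midfoot"])
        for name in ("medial heel", "lateral heel", "medial forefoot",
                     "middle forefoot", "lateral forefoot", "hallux"):
            np.testing.assert_array_equal(seven[name], eight[name])

    def test_empty_footprint_rejected(self):
        pmap = fm.PressureMap([0.0, 5.0], [0.0, 5.0], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            fm.partition_regions(pmap, fm.RegionScheme.seven())


class TestPeaks:
    def test_constant_map_every_region_peaks_at_constant(self):
        x = np.arange(-30.0, 31.0, 5.0)
        y = np.arange(0.0, 251.0, 5.0)
        pmap = fm.PressureMap(x, y, np.full((len(y), len(x)), 100.0))
        masks = fm.partition_regions(pmap, fm.RegionScheme.seven())
        peaks = fm.region_peaks(pmap, masks)
        assert all(v == 100.0 for v in peaks.values())

    def test_point_mass_in_heel(self, two_lobed):
        values = two_lobed.values.copy()
        masks = fm.partition_regions(two_lobed, fm.RegionScheme.seven())
        heel_cells = np.argwhere(masks["medial heel"])
        i, j = heel_cells[0]
        values[i, j] = 500.0
        spiked = fm.PressureMap(two_lobed.x, two_lobed.y, values)
        peaks = fm.region_peaks(spiked, fm.partition_regions(spiked, fm.RegionScheme.seven()))
        assert peaks["medial heel"] == 500.0

    def test_matches_per_mask_maximum_oracle(self, two_lobed):
        masks = fm.partition_regions(two_lobed, fm.RegionScheme.eight())
        peaks = fm.region_peaks(two_lobed, masks)
        for name, mask in masks.items():
            expected = max((two_lobed.values[idx] for idx in zip(*np.where(mask))),
                           default=0.0)
            assert peaks[name] == expected

    def test_empty_region_warns_and_reports_zero(self, two_lobed):
        masks = {"void": np.zeros_like(two_lobed.values, dtype=bool)}
        with pytest.warns(UserWarning, match="void"):
            peaks = fm.region_peaks(two_lobed, masks)
        assert peaks["void"] == 0.0


class TestComparePaired:
    def test_identical_samples_degenerate_p_one(self):
        a = [100.0, 120.0, 90.0, 80.0]
        res = fm.compare_paired(a, a)
        assert res.p_value == 1.0
        assert res.test == "wilcoxon"
        assert not res.significant

    def test_wilcoxon_exact_p_for_six_positive_differences(self):
        # alpha=1 makes the normality gate always fail, deterministically
        # selecting the signed-rank branch for this oracle check
        b = np.zeros(6)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = fm.compare_paired(a, b, alpha=1.0)
        assert res.test == "wilcoxon"
        assert res.p_value == pytest.approx(2 * (0.5 ** 6), abs=1e-12)
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(a - b), abs=1e-12)

    def test_wilcoxon_branch_matches_enumeration_oracle(self):
        # heavy-tailed differences reliably fail Shapiro-Wilk
        diffs = np.array([0.1, 0.2, 0.15, 0.12, 0.18, 0.11, 0.14, 25.0, -0.1, 30.0])
        res = fm.compare_paired(diffs, np.zeros_like(diffs), alpha=0.05)
        assert res.test == "wilcoxon"
        assert res.p_value == pytest.approx(wilcoxon_enumeration_p(diffs), abs=1e-12)

    def test_paired_t_branch_matches_hand_formula(self):
        rng = np.random.default_rng(42)
        b = rng.normal(100.0, 10.0, size=12)
        d = rng.normal(2.0, 3.0, size=12)
        a = b + d
        res = fm.compare_paired(a, b)
        assert res.test == "paired-t"
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        p_hand = 2 * sps.t.sf(abs(t_hand), df=len(d) - 1)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_branch_is_function_of_normality_p(self):
        rng = np.random.default_rng(1)
        b = rng.normal(size=10)
        a = b + rng.normal(1.0, 0.5, size=10)
        norm_p = float(sps.shapiro(a - b).pvalue)
        res = fm.compare_paired(a, b)
        assert res.normality_p == pytest.approx(norm_p)
        assert res.test == ("paired-t" if norm_p >= 0.05 else "wilcoxon")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fm.compare_paired([1.0, 2.0], [1.0, 2.0])


class TestAgreement:
    def test_perfect_agreement(self):
        m = [113.0, 91.0, 60.0, 45.0, 30.0]
        res = fm.agreement(m, m)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.mean_offset == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_constant_shift(self):
        m = np.array([113.0, 91.0, 60.0, 45.0, 30.0])
        res = fm.agreement(m, m + 10.0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.mean_offset == pytest.approx(10.0)
        assert res.loa_lower == pytest.approx(10.0)
        assert res.loa_upper == pytest.approx(10.0)

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(20, 150, size=8)
        p = m + rng.normal(11.0, 8.0, size=8)
        res = fm.agreement(m, p)
        r_hand = (np.mean((m - m.mean()) * (p - p.mean()))
                  / (m.std() * p.std()))
        assert res.pearson_r == pytest.approx(r_hand, rel=1e-12)
        d = p - m
        assert res.mean_offset == pytest.approx(d.mean(), rel=1e-12)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), rel=1e-12)

    def test_offset_shifts_by_added_constant(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(20, 150, size=8)
        p = m + rng.normal(0.0, 5.0, size=8)
        base = fm.agreement(m, p)
        shifted = fm.agreement(m, p + 7.5)
        assert shifted.mean_offset == pytest.approx(base.mean_offset + 7.5, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fm.agreement([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
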