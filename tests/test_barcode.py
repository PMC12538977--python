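"""Spectral-barcode extraction: rank-test oracle equivalence, region merging,
area features and significance ranking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import ramanbarcode as rb
from ramanbarcode.barcode import BarcodeRegion, ShiftPValueTrack
from ramanbarcode.spectra import Spectrum


def exact_mw_pvalue(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    observed = u_stat(a, b)
    mu = na * len(b) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(ga, gb)
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def make_track(p, direction=None, axis=None):
    p = np.asarray(p, dtype=float)
    if axis is None:
        axis = np.arange(p.size, dtype=float)
    if direction is None:
        direction = np.ones_like(p)
    return ShiftPValueTrack(axis, p, np.zeros_like(p), np.asarray(direction, float))


class TestMannWhitneyPerShift:
    def test_single_channel_exact_p(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[4.0], [5.0], [6.0]])
        track = rb.mannwhitney_per_shift(a, b)
        assert track.p[0] == pytest.approx(0.1)  # 2/20 arrangements as extreme
        assert track.direction[0] == -1

    def test_identical_distributions_p_one(self):
        a = np.array([[1.0], [2.0], [3.0]])
        track = rb.mannwhitney_per_shift(a, a.copy())
        assert track.p[0] == pytest.approx(1.0)

    def test_label_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal((5, 8)), rng.standard_normal((6, 8)) + 1
        t1 = rb.mannwhitney_per_shift(a, b)
        t2 = rb.mannwhitney_per_shift(b, a)
        assert np.allclose(t1.p, t2.p)
        assert np.array_equal(t1.direction, -t2.direction)

    @pytest.mark.parametrize("na,nb", [(2, 2), (3, 4), (5, 3), (6, 6)])
    def test_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(10):
            a = rng.standard_normal((na, 1))
            b = rng.standard_normal((nb, 1))
            track = rb.mannwhitney_per_shift(a, b)
            assert track.p[0] == pytest.approx(exact_mw_pvalue(a[:, 0], b[:, 0]), abs=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            rb.mannwhitney_per_shift(np.zeros((1, 4)), np.zeros((5, 4)))

    def test_patient_aggregation_uses_patient_means(self, class_split):
        ad, non, _ = class_split
        track = rb.mannwhitney_per_shift(ad, non, aggregate="patient")
        oracle = rb.mannwhitney_per_shift(ad.patient_means()[1], non.patient_means()[1])
        assert np.allclose(track.p, oracle.p)


class TestExtractRegions:
    def test_two_separate_runs(self):
        track = make_track([0.5, 0.001, 0.001, 0.5, 0.001, 0.5])
        regions = rb.extract_regions(track, alpha=0.01, max_gap=0, min_width=1)
        assert len(regions) == 2

    def test_no_significant_channels(self):
        track = make_track([0.5] * 10)
        assert rb.extract_regions(track) == []

    def test_gap_merging(self):
        track = make_track([0.001, 0.5, 0.001])
        regions = rb.extract_regions(track, alpha=0.01, max_gap=1, min_width=1)
        assert len(regions) == 1
        assert (regions[0].lo, regions[0].hi) == (0.0, 2.0)

    def test_opposite_directions_never_merge(self):
        track = make_track([0.001, 0.5, 0.001], direction=[1, 1, -1])
        regions = rb.extract_regions(track, alpha=0.01, max_gap=1, min_width=1)
        assert len(regions) == 2

    def test_min_width_filter(self):
        track = make_track([0.001, 0.001, 0.5, 0.5, 0.001, 0.001, 0.001])
        regions = rb.extract_regions(track, alpha=0.01, max_gap=0, min_width=3)
        assert len(regions) == 1 and regions[0].lo == 4.0

    def test_rank_order_by_min_p_with_tie_break(self):
        track = make_track([0.002, 0.5, 0.001, 0.5, 0.001])
        regions = rb.extract_regions(track, alpha=0.01, max_gap=0, min_width=1)
        assert [r.rank for r in regions] == [1, 2, 3]
        assert regions[0].lo == 2.0  # smallest p first, then lower wavenumber
        assert regions[1].lo == 4.0

    def test_brute_force_run_merging_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = rng.uniform(size=40)
            p[rng.uniform(size=40) < 0.3] = 0.001
            max_gap, min_width = int(rng.integers(0, 4)), int(rng.integers(1, 4))
            track = make_track(p)
            got = {
                (r.lo, r.hi)
                for r in rb.extract_regions(track, 0.01, max_gap, min_width)
            }
            # oracle: scan significant indices, bridge small gaps, drop short runs
            sig = [i for i in range(40) if p[i] < 0.01]
            runs = []
            for i in sig:
                if runs and i - runs[-1][-1] <= max_gap + 1:
                    runs[-1].append(i)
                else:
                    runs.append([i])
            want = {
                (float(r[0]), float(r[-1]))
                for r in runs
                if r[-1] - r[0] + 1 >= min_width
            }
            assert got == want


class TestRegionArea:
    def test_constant_intensity_times_width(self):
        axis = np.linspace(0, 10, 11)
        s = Spectrum(axis, np.full(11, 2.0))
        region = BarcodeRegion(2.0, 7.0, 1, 0.001, rank=1)
        assert rb.region_area(s, region) == pytest.approx(2.0 * 5.0)

    def test_triangle_example(self):
        s = Spectrum(np.array([0.0, 1.0, 2.0]), np.array([1.0, 3.0, 1.0]))
        assert rb.region_area(s, BarcodeRegion(0, 2, 1, 0.001, 1)) == pytest.approx(4.0)

    def test_single_channel_region_zero(self):
        s = Spectrum(np.arange(5.0), np.ones(5))
        assert rb.region_area(s, BarcodeRegion(2.0, 2.0, 1, 0.001, 1)) == 0.0

    def test_region_outside_axis_rejected(self):
        s = Spectrum(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            rb.region_area(s, BarcodeRegion(3.0, 9.0, 1, 0.001, 1))

    def test_linearity(self):
        rng = np.random.default_rng(1)
        axis = np.linspace(0, 20, 50)
        y1, y2 = rng.standard_normal(50), rng.standard_normal(50)
        region = BarcodeRegion(3.0, 15.0, 1, 0.001, 1)
        a1 = rb.region_area(Spectrum(axis, y1), region)
        a2 = rb.region_area(Spectrum(axis, y2), region)
        combo = rb.region_area(Spectrum(axis, 2 * y1 + 3 * y2), region)
        assert combo == pytest.approx(2 * a1 + 3 * a2)


class TestFeatureTable:
    def test_constant_spectra_give_constant_columns(self):
        axis = np.linspace(0, 10, 21)
        rows = np.full((4, 21), 3.0)
        sset = rb.SpectrumSet(axis, rows, np.array(["a", "a", "b", "b"], dtype=object), [0, 1, 0, 1])
        barcode = rb.Barcode([BarcodeRegion(1.0, 4.0, 1, 0.001, rank=1)])
        table = rb.build_feature_table(sset, barcode)
        assert table.shape == (4, 1)
        assert np.allclose(table.iloc[:, 0], 3.0 * 3.0)

    def test_row_order_follows_spectra(self, processed_small):
        _, processed, _, _ = processed_small
        barcode = rb.Barcode([BarcodeRegion(1000.0, 1012.0, 1, 0.001, rank=1)])
        table = rb.build_feature_table(processed, barcode)
        perm = np.random.default_rng(0).permutation(len(processed))
        table_p = rb.build_feature_table(processed.subset(perm), barcode)
        merged = table.reindex(table_p.index)
        assert np.allclose(merged.to_numpy(), table_p.to_numpy())

    def test_injected_effect_separates_classes(self, class_split):
        ad, non, _ = class_split
        barcode = rb.Barcode([BarcodeRegion(1003.0, 1010.0, 1, 0.001, rank=1)])
        a = rb.build_feature_table(ad, barcode).iloc[:, 0].groupby("patient_id").mean()
        b = rb.build_feature_table(non, barcode).iloc[:, 0].groupby("patient_id").mean()
        # region is up-regulated in the disease class by construction
        assert a.mean() > b.mean()


class TestBuildAndRank:
    def test_end_to_end_barcode_has_consistent_ranks(self, class_split):
        ad, non, _ = class_split
        barcode = rb.build_barcode(ad, non, aggregate="patient")
        ranks = sorted(r.rank for r in barcode.regions)
        assert ranks == list(range(1, len(barcode) + 1))
        starts = [r.lo for r in sorted(barcode.regions, key=lambda r: r.lo)]
        assert starts == sorted(starts)

    def test_rank_features_puts_strongest_effect_first(self):
        rng = np.random.default_rng(2)
        n = 40
        labels = np.array(["AD"] * n + ["non-AD"] * n)
        strong = np.concatenate([rng.normal(3, 1, n), rng.normal(0, 1, n)])
        null = rng.standard_normal(2 * n)
        table = pd.DataFrame(
            {"A(10-20)": null, "A(30-40)": strong},
            index=pd.MultiIndex.from_arrays(
                [[f"p{i}" for i in range(2 * n)], [0] * (2 * n)],
                names=["patient_id", "replicate"],
            ),
        )
        barcode = rb.Barcode(
            [
                BarcodeRegion(10.0, 20.0, 1, 0.5, rank=1),
                BarcodeRegion(30.0, 40.0, 1, 0.5, rank=2),
            ]
        )
        ranked = rb.rank_features(table, labels, barcode)
        assert ranked.by_rank()[0].lo == 30.0

    def test_rank_features_idempotent(self, class_split):
        ad, non, records = class_split
        barcode = rb.build_barcode(ad, non, aggregate="patient")
        both = rb.SpectrumSet(
            ad.axis,
            np.vstack([ad.intensities, non.intensities]),
            np.concatenate([ad.patient_ids, non.patient_ids]),
            np.concatenate([ad.replicates, non.replicates]),
        )
        table = rb.build_feature_table(both, barcode)
        labels = np.array(
            ["AD"] * len(ad) + ["non-AD"] * len(non)
        )
        once = rb.rank_features(table, labels, barcode)
        table2 = rb.build_feature_table(both, once)
        twice = rb.rank_features(table2, labels, once)
        assert [r.lo for r in once.by_rank()] == [r.lo for r in twice.by_rank()]
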