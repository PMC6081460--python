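import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncomark.coverage import bin_genome
from oncomark.errors import InvalidInputError
from oncomark.region_calling import (
    BinSet,
    EnrichmentConfig,
    FactorClassification,
    Region,
    classify_by_factor,
    merge_and_filter,
    nearest_rank_percentile,
    overlap_classes,
    quantile_summary,
    region_set_to_binset,
    scaled_region_matrix,
    select_enriched_genic_bins,
)

from conftest import make_track


def binset(rows):
    """rows: (chrom, start, end, value[, source])"""
    return BinSet(
        chrom=np.array([r[0] for r in rows], dtype=object),
        start=np.array([r[1] for r in rows], dtype=np.int64),
        end=np.array([r[2] for r in rows], dtype=np.int64),
        value=np.array([r[3] for r in rows], dtype=float),
        source=np.array(
            [r[4] if len(r) > 4 else "WT" for r in rows], dtype=object
        ),
    )


def brute_force_merge(rows, merge_distance):
    """O(n^2) repeated pairwise merging until fixpoint (oracle)."""
    items = [
        {"chrom": c, "start": s, "end": e, "vals": [v]} for c, s, e, v, *_ in rows
    ]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(len(items)):
                if i == j:
                    continue
                a, b = items[i], items[j]
                if a["chrom"] != b["chrom"]:
                    continue
                gap = max(a["start"], b["start"]) - min(a["end"], b["end"])
                if gap <= merge_distance:
                    a["start"] = min(a["start"], b["start"])
                    a["end"] = max(a["end"], b["end"])
                    a["vals"] += b["vals"]
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(
        (it["chrom"], it["start"], it["end"], float(np.mean(it["vals"])), len(it["vals"]))
        for it in items
    )


class TestNearestRankPercentile:
    def test_enumerated_oracle(self):
        # nearest rank: smallest value with at least p% of values <= it
        values = list(range(1, 101))
        for p in (25, 50, 75, 90, 95):
            thr = nearest_rank_percentile(values, p)
            below_or_equal = sum(v <= thr for v in values)
            assert below_or_equal >= p
            assert sum(v <= thr - 1 for v in values) < p

    def test_small_n(self):
        assert nearest_rank_percentile([7.0], 95) == 7.0
        assert nearest_rank_percentile([1.0, 2.0], 50) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            nearest_rank_percentile([], 50)


class TestSelectEnrichedGenicBins:
    def setup_method(self):
        self.grid = bin_genome({"c": 20_000}, 200)  # 100 bins
        self.genes = [("c", 0, 20_000)]
        self.config = EnrichmentConfig()

    def test_top_five_selected(self):
        wt = make_track(self.grid, np.arange(1, 101, dtype=float))
        mut = make_track(self.grid, np.zeros(100))
        bins = select_enriched_genic_bins(wt, mut, self.genes, self.config)
        assert len(bins) == 5
        assert sorted(bins.value) == [96, 97, 98, 99, 100]
        assert set(bins.source) == {"WT"}

    def test_either_condition_rule(self):
        wt = make_track(self.grid, np.zeros(100))
        mut_vals = np.ones(100)
        mut_vals[3] = 50.0
        mut = make_track(self.grid, mut_vals)
        bins = select_enriched_genic_bins(wt, mut, self.genes, self.config)
        assert list(bins.start) == [600]
        assert list(bins.source) == ["mutant"]

    def test_genic_restriction(self):
        wt_vals = np.zeros(100)
        wt_vals[50] = 100.0  # bin [10000, 10200) — outside the gene below
        wt_vals[2] = 90.0
        wt = make_track(self.grid, wt_vals)
        mut = make_track(self.grid, np.zeros(100))
        genes = [("c", 0, 5_000)]
        bins = select_enriched_genic_bins(wt, mut, genes, self.config)
        assert 10_000 not in bins.start
        assert 400 in bins.start

    def test_empty_genes_rejected(self):
        wt = make_track(self.grid, np.zeros(100))
        with pytest.raises(InvalidInputError):
            select_enriched_genic_bins(wt, wt, [], self.config)


class TestMergeAndFilter:
    def setup_method(self):
        self.config = EnrichmentConfig()

    def test_gap_100_merges(self):
        regions = merge_and_filter(
            binset([("c", 0, 200, 2.0), ("c", 300, 500, 4.0)]), self.config
        )
        assert len(regions) == 1
        r = regions.regions[0]
        assert (r.start, r.end, r.n_bins) == (0, 500, 2)
        assert r.score == pytest.approx(3.0)

    def test_gap_above_100_does_not_merge(self):
        regions = merge_and_filter(
            binset([("c", 0, 200, 2.0), ("c", 301, 501, 4.0)]), self.config
        )
        assert len(regions) == 2

    def test_long_region_excluded(self):
        regions = merge_and_filter(
            binset([("c", 0, 200, 1.0), ("c", 200, 400, 1.0), ("c", 400, 600, 1.0)]),
            self.config,
        )
        assert len(regions) == 0
        assert [reason for _, reason in regions.excluded] == ["length"]

    def test_extreme_top_removal_count(self):
        rows = [("c", i * 400, i * 400 + 200, float(i)) for i in range(10_000)]
        regions = merge_and_filter(binset(rows), self.config)
        extreme = [(r, why) for r, why in regions.excluded if why == "extreme"]
        assert len(extreme) == math.ceil(10_000 * 0.0001) == 1
        assert extreme[0][0].score == 9999.0

    def test_empty_input(self):
        assert len(merge_and_filter(binset([]), self.config)) == 0

    def test_source_condition_propagation(self):
        regions = merge_and_filter(
            binset([("c", 0, 200, 1.0, "WT"), ("c", 200, 400, 1.0, "mutant")]),
            self.config,
        )
        assert regions.regions[0].source_condition == "either"

    def test_matches_brute_force(self, rng):
        cfg = EnrichmentConfig(max_region_length=10**9, extreme_top_fraction=0.5**30)
        for _ in range(25):
            n = int(rng.integers(1, 60))
            rows = []
            for _ in range(n):
                chrom = "c" + str(rng.integers(1, 3))
                start = int(rng.integers(0, 40)) * 200
                rows.append((chrom, start, start + 200, float(rng.integers(0, 50))))
            # drop duplicate bins (same chrom/start)
            rows = list({(c, s): (c, s, e, v) for c, s, e, v in rows}.values())
            merged = merge_and_filter(binset(rows), cfg)
            got = sorted(
                (r.chrom, r.start, r.end, r.score, r.n_bins)
                for r in list(merged) + [x for x, _ in merged.excluded]
            )
            expected = brute_force_merge(rows, cfg.merge_distance)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g[:3] == e[:3]
                assert g[3] == pytest.approx(e[3])
                assert g[4] == e[4]

    def test_idempotence(self, rng):
        rows = [
            ("c", int(s) * 200, int(s) * 200 + 200, float(v))
            for s, v in zip(rng.integers(0, 100, 40), rng.integers(1, 30, 40))
        ]
        rows = list({(c, s): (c, s, e, v) for c, s, e, v in rows}.values())
        cfg = EnrichmentConfig(max_region_length=10**9, extreme_top_fraction=0.5**30)
        once = merge_and_filter(binset(rows), cfg)
        twice = merge_and_filter(region_set_to_binset(once), cfg)
        assert [(r.chrom, r.start, r.end) for r in once] == [
            (r.chrom, r.start, r.end) for r in twice
        ]

    def test_region_count_bounded_by_bin_count(self, rng):
        rows = [
            ("c", int(s) * 200, int(s) * 200 + 200, 1.0)
            for s in sorted(set(rng.integers(0, 200, 50).tolist()))
        ]
        regions = merge_and_filter(binset(rows), EnrichmentConfig(max_region_length=10**9))
        assert len(regions) + len(regions.excluded) <= len(rows)


class TestClassifyByFactor:
    def setup_method(self):
        self.grid = bin_genome({"c": 20_000}, 200)
        self.config = EnrichmentConfig(
            factor_enriched_percentile=75, factor_depleted_percentile=25
        )
        self.regions = [
            Region("c", i * 200, i * 200 + 200, 1.0, 1) for i in range(100)
        ]

    def test_percentile_labels(self):
        factor = make_track(self.grid, np.arange(1, 101, dtype=float))
        cls = classify_by_factor(self.regions, factor, self.config)
        assert (cls.labels == "enriched").sum() == 25   # values 76..100
        assert (cls.labels == "depleted").sum() == 24   # values 1..24
        assert (cls.labels == "neither").sum() == 51

    def test_constant_track_all_neither(self):
        factor = make_track(self.grid, np.full(100, 3.0))
        cls = classify_by_factor(self.regions, factor, self.config)
        assert set(cls.labels) == {"neither"}

    def test_zero_coverage_region_depleted(self):
        vals = np.arange(1, 101, dtype=float)
        vals[7] = 0.0
        factor = make_track(self.grid, vals)
        cls = classify_by_factor(self.regions, factor, self.config)
        assert cls.labels[7] == "depleted"

    def test_too_few_regions_rejected(self):
        factor = make_track(self.grid, np.arange(100, dtype=float))
        with pytest.raises(InvalidInputError):
            classify_by_factor(self.regions[:3], factor, self.config)

    def test_permutation_invariance(self, rng):
        factor = make_track(self.grid, rng.random(100) * 10)
        cls = classify_by_factor(self.regions, factor, self.config)
        perm = rng.permutation(100)
        cls_perm = classify_by_factor(
            [self.regions[i] for i in perm], factor, self.config
        )
        assert list(cls_perm.labels) == [cls.labels[i] for i in perm]


class TestOverlapClasses:
    def _cls(self, factor_id, labels):
        labels = np.array(labels, dtype=object)
        return FactorClassification(
            factor_id=factor_id,
            labels=labels,
            scores=np.zeros(len(labels)),
            enriched_threshold=0.0,
            depleted_threshold=0.0,
        )

    def test_triple_overlap(self):
        a = self._cls("A", ["enriched", "enriched"])
        b = self._cls("B", ["enriched", "neither"])
        c = self._cls("C", ["enriched", "neither"])
        counts = overlap_classes([a, b, c])
        assert counts[("A", "B", "C")] == 1
        assert counts[("A",)] == 1
        assert counts[("A", "B")] == 0

    def test_depletion_exclusion(self):
        a = self._cls("A", ["enriched"])
        b = self._cls("B", ["depleted"])
        counts = overlap_classes([a, b])
        assert counts[("A", "B")] == 0
        assert counts[("A",)] == 1  # still counts for A alone

    def test_empty(self):
        assert overlap_classes([]) == {}
        counts = overlap_classes([self._cls("A", []), self._cls("B", [])])
        assert all(v == 0 for v in counts.values())

    def test_mismatched_sets_rejected(self):
        with pytest.raises(InvalidInputError):
            overlap_classes([self._cls("A", ["enriched"]), self._cls("B", [])])


class TestScaledRegionMatrix:
    def setup_method(self):
        self.grid = bin_genome({"c": 100_000}, 200)

    def test_constant_field(self):
        track = make_track(self.grid, np.full(self.grid.n_bins, 4.0))
        regions = [Region("c", 10_000, 10_400, 1.0, 2)]
        m = scaled_region_matrix(regions, track)
        assert m.matrix.shape == (1, 2 * m.n_flank_cols + m.n_body_cols)
        np.testing.assert_allclose(m.matrix, 4.0)

    def test_blacklist_exclusion(self):
        track = make_track(self.grid, np.ones(self.grid.n_bins))
        regions = [
            Region("c", 10_000, 10_400, 1.0, 2),
            Region("c", 50_000, 50_400, 1.0, 2),
        ]
        m = scaled_region_matrix(regions, track, blacklist=[("c", 50_100, 50_200)])
        assert len(m.regions) == 1
        assert m.regions[0].start == 10_000
        with pytest.raises(InvalidInputError):
            scaled_region_matrix(regions, track, blacklist=[("c", 0, 100_000)])

    def test_interpolation_oracle_two_bins(self):
        # 400 bp region over bins valued v1, v2; body columns sample the
        # linear interpolant between the bin centers (clamped at the edges)
        vals = np.zeros(self.grid.n_bins)
        i0 = 10_000 // 200
        v1, v2 = 3.0, 9.0
        vals[i0], vals[i0 + 1] = v1, v2
        track = make_track(self.grid, vals)
        m = scaled_region_matrix(
            [Region("c", 10_000, 10_400, 1.0, 2)], track, body_length=500, flank=0
        )
        n = m.n_body_cols
        assert n == 3  # ceil(500 / 200)
        centers = (np.arange(n) + 0.5) / n  # relative positions of columns
        expected = np.interp(centers, [0.25, 0.75], [v1, v2])
        np.testing.assert_allclose(m.matrix[0], expected)

    def test_single_bin_region_fills_body(self):
        vals = np.zeros(self.grid.n_bins)
        vals[5] = 7.0
        track = make_track(self.grid, vals)
        m = scaled_region_matrix([Region("c", 1_000, 1_100, 1.0, 1)], track, flank=0)
        np.testing.assert_allclose(m.matrix[0], 7.0)

    def test_flanks_native_resolution_and_zero_padding(self):
        track = make_track(self.grid, np.ones(self.grid.n_bins))
        m = scaled_region_matrix([Region("c", 0, 400, 1.0, 2)], track, flank=1000)
        assert m.n_flank_cols == 5
        np.testing.assert_allclose(m.matrix[0, :5], 0.0)  # off-chromosome
        np.testing.assert_allclose(m.matrix[0, 5:], 1.0)


class TestQuantileSummary:
    def test_linear_interpolation_oracle(self):
        got = quantile_summary(np.arange(1, 101, dtype=float))
        assert got == pytest.approx((10.9, 25.75, 50.5, 75.25, 90.1))

    def test_degenerate(self):
        assert quantile_summary([5.0]) == pytest.approx((5.0,) * 5)
        assert quantile_summary([2.0] * 9) == pytest.approx((2.0,) * 5)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            quantile_summary([])

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_quantiles(self, values):
        q = quantile_summary(values)
        assert all(a <= b + 1e-9 for a, b in zip(q, q[1:]))
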