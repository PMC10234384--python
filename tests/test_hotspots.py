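"""Peak calling, Tukey size filter, coldspots, classification, comparison."""

import numpy as np
import pandas as pd
import pytest

from recmap.hotspots import (
    ChromatinMap,
    call_coldspots,
    call_hotspots,
    classify_chromatin,
    compare_hotspots,
    summarize,
    tukey_filter,
)
from recmap.linkmap import build_map
from recmap.marey import MareyMap, RateProfile, fit_spline, isotonize, rate_profile
from recmap.qc import run_qc
from recmap.simulate import default_marker_grid, make_landscape, simulate_ril_population

EU = "euchromatic"
HET = "heterochromatic"


def make_profile(rates, step=10_000, chrom="c1") -> RateProfile:
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    pos = (np.arange(n) + 0.5) * step
    return RateProfile(
        positions={chrom: pos}, rates={chrom: rates},
        widths={chrom: np.full(n, float(step))},
        grid_step=step, method="synthetic",
    )


def hs_frame(records) -> pd.DataFrame:
    rows = []
    for chrom, start, end, cls in records:
        rows.append({
            "chromosome": chrom, "start": start, "end": end,
            "peak": (start + end) // 2, "peak_rate": 5.0, "mean_rate": 3.0,
            "size": end - start, "chromatin": cls, "population": "p",
            "kind": "hotspot",
        })
    return pd.DataFrame(rows)


class TestCallHotspots:
    def test_flat_profile_empty(self):
        hs = call_hotspots(make_profile(np.full(100, 2.0)))
        assert len(hs) == 0

    def test_single_bump_one_hotspot(self):
        rates = np.full(100, 2.0)
        rates[48:52] = [6, 10, 9, 5]
        hs = call_hotspots(make_profile(rates), window=5, min_fold=2.0)
        assert len(hs) == 1
        row = hs.iloc[0]
        assert row["start"] <= 49 * 10_000 + 5_000 <= row["end"]
        assert row["peak_rate"] == 10.0
        assert row["kind"] == "hotspot"

    def test_peak_must_clear_fold_threshold(self):
        rates = np.full(100, 2.0)
        rates[50] = 3.5  # local max but < 2x median
        assert len(call_hotspots(make_profile(rates), min_fold=2.0)) == 0

    def test_boundaries_extend_to_threshold(self):
        rates = np.full(200, 1.0)
        rates[95:106] = [2, 3, 5, 7, 9, 10, 9, 7, 5, 3, 2]
        hs = call_hotspots(make_profile(rates), window=10, min_fold=2.0,
                           boundary_frac=0.5)
        row = hs.iloc[0]
        # boundary threshold = max(bg=1, 0.5*10=5): indices 97..103 included
        assert row["start"] == 97 * 10_000
        assert row["end"] == 104 * 10_000
        assert row["size"] == row["end"] - row["start"]

    def test_overlapping_candidates_merged_keeping_higher_peak(self):
        rates = np.full(300, 1.0)
        rates[100:110] = 8.0
        rates[104] = 12.0
        rates[115:125] = 8.0
        rates[120] = 10.0
        hs = call_hotspots(make_profile(rates), window=3, min_fold=2.0,
                           boundary_frac=0.1)
        assert len(hs) == 1
        assert hs.iloc[0]["peak_rate"] == 12.0

    def test_per_class_background(self, chromatin_map_c1):
        # heterochromatic bump small in absolute rate but large vs class bg
        n = 2000  # 20 Mbp at 10 kb
        rates = np.full(n, 5.0)
        rates[800:1200] = 0.3  # het block (8-12 Mbp)
        rates[995:1006] = 1.5
        rates[1000] = 2.0
        hs = call_hotspots(make_profile(rates), chromatin_map_c1,
                           window=10, min_fold=2.0)
        het = hs[hs["chromatin"] == HET]
        assert len(het) == 1
        assert het.iloc[0]["peak_rate"] == 2.0

    def test_coordinates_half_open_invariants(self):
        rates = np.full(100, 2.0)
        rates[30] = 10.0
        rates[70] = 9.0
        hs = call_hotspots(make_profile(rates), window=5)
        for row in hs.itertuples():
            assert row.start < row.end
            assert row.start <= row.peak < row.end
            assert row.size == row.end - row.start


class TestTukeyFilter:
    def test_hand_computed_fence(self):
        hs = hs_frame([("c1", 0, s * 1000, EU) for s in (10, 20, 30, 40, 1000)])
        out = tukey_filter(hs)
        assert sorted(out["size"]) == [10_000, 20_000, 30_000, 40_000]

    def test_all_equal_none_removed(self):
        hs = hs_frame([("c1", 0, 50_000, EU)] * 6)
        assert len(tukey_filter(hs)) == 6

    def test_small_groups_unfiltered(self):
        hs = hs_frame([("c1", 0, 10_000, EU), ("c1", 0, 20_000, EU),
                       ("c1", 0, 9_000_000, EU)])
        assert len(tukey_filter(hs)) == 3

    def test_classes_filtered_independently(self):
        eu = [("c1", 0, s * 1000, EU) for s in (10, 20, 30, 40, 1000)]
        het = [("c1", 0, s * 1000, HET) for s in (500, 600, 700, 800)]
        out = tukey_filter(hs_frame(eu + het))
        assert len(out) == 8  # only the 1000-kb euchromatic record removed

    def test_brute_force_oracle(self, rng):
        # oracle: sort, type-7 quantiles by index arithmetic, fence rule
        def oracle(sizes):
            s = np.sort(sizes)
            def q(p):
                h = (len(s) - 1) * p
                lo = int(np.floor(h))
                hi = min(lo + 1, len(s) - 1)
                return s[lo] + (h - lo) * (s[hi] - s[lo])
            fence = q(0.75) + 1.5 * (q(0.75) - q(0.25))
            return sizes <= fence

        for _ in range(1000):
            n = int(rng.integers(4, 40))
            sizes = rng.integers(1_000, 2_000_000, n)
            hs = hs_frame([("c1", 0, int(s), EU) for s in sizes])
            out = tukey_filter(hs)
            assert sorted(out["size"]) == sorted(sizes[oracle(sizes)])

    def test_empty_set(self):
        from recmap.hotspots import empty_hotspot_set
        assert len(tukey_filter(empty_hotspot_set())) == 0


class TestColdspots:
    def test_flat_profile_no_coldspots(self):
        assert len(call_coldspots(make_profile(np.full(100, 5.0)),
                                  min_len_bp=100_000)) == 0

    def test_gap_detected(self):
        rates = np.full(1000, 5.0)
        rates[400:500] = 0.0  # 1 Mbp gap
        cs = call_coldspots(make_profile(rates), max_frac=0.2,
                            min_len_bp=500_000)
        assert len(cs) == 1
        row = cs.iloc[0]
        assert row["start"] <= 400 * 10_000 and row["end"] >= 500 * 10_000
        assert row["kind"] == "coldspot"

    def test_short_runs_ignored(self):
        rates = np.full(1000, 5.0)
        rates[400:410] = 0.0  # 100 kb < min_len
        assert len(call_coldspots(make_profile(rates), min_len_bp=500_000)) == 0

    def test_hotspots_and_coldspots_disjoint(self, rng):
        for _ in range(100):
            rates = np.exp(rng.normal(1.0, 0.8, 400))
            prof = make_profile(rates)
            hs = call_hotspots(prof, window=5, min_fold=2.0)
            cs = call_coldspots(prof, max_frac=0.2, min_len_bp=50_000)
            for h in hs.itertuples():
                for c in cs.itertuples():
                    assert min(h.end, c.end) <= max(h.start, c.start)


class TestClassify:
    def test_peak_inside_het(self, chromatin_map_c1):
        hs = hs_frame([("c1", 9_000_000, 9_100_000, "?")])
        out = classify_chromatin(hs, chromatin_map_c1)
        assert out.iloc[0]["chromatin"] == HET

    def test_boundary_half_open(self, chromatin_map_c1):
        # peak exactly at the start of the 12 Mbp euchromatic interval
        hs = hs_frame([("c1", 11_950_000, 12_050_000, "?")])
        hs.loc[0, "peak"] = 12_000_000
        out = classify_chromatin(hs, chromatin_map_c1)
        assert out.iloc[0]["chromatin"] == EU

    def test_partition(self, chromatin_map_c1, rng):
        peaks = rng.integers(0, 20_000_000, 50)
        hs = hs_frame([("c1", int(p), int(p) + 1000, "?") for p in peaks])
        hs["peak"] = peaks
        out = classify_chromatin(hs, chromatin_map_c1)
        n_eu = (out["chromatin"] == EU).sum()
        n_het = (out["chromatin"] == HET).sum()
        assert n_eu + n_het == len(out)


class TestCompare:
    def test_overlap_shared(self):
        a = hs_frame([("c1", 100_000, 200_000, EU)])
        b = hs_frame([("c1", 150_000, 250_000, EU)])
        _, n_shared, fa, fb = compare_hotspots(a, b)
        assert n_shared == 1 and fa == 1.0 and fb == 1.0

    def test_half_open_touch_not_shared(self):
        a = hs_frame([("c1", 100_000, 200_000, EU)])
        b = hs_frame([("c1", 200_000, 300_000, EU)])
        _, n_shared, _, _ = compare_hotspots(a, b)
        assert n_shared == 0

    def test_different_chromosomes_not_shared(self):
        a = hs_frame([("c1", 100_000, 200_000, EU)])
        b = hs_frame([("c2", 100_000, 200_000, EU)])
        assert compare_hotspots(a, b)[1] == 0

    def test_identical_sets_full_fractions(self):
        a = hs_frame([("c1", 0, 100_000, EU), ("c1", 500_000, 600_000, EU)])
        _, n, fa, fb = compare_hotspots(a, a.copy())
        assert n == 2 and fa == 1.0 and fb == 1.0

    def test_symmetry_of_shared_pairs(self, rng):
        def random_set(n):
            starts = np.sort(rng.integers(0, 50_000_000, n))
            return hs_frame([("c1", int(s), int(s + rng.integers(10_000, 400_000)), EU)
                             for s in starts])
        a, b = random_set(15), random_set(15)
        pairs_ab = compare_hotspots(a, b)[0]
        pairs_ba = compare_hotspots(b, a)[0]
        fwd = {(r.a_start, r.a_end, r.b_start, r.b_end) for r in pairs_ab.itertuples()}
        rev = {(r.b_start, r.b_end, r.a_start, r.a_end) for r in pairs_ba.itertuples()}
        assert fwd == rev


class TestSummarize:
    def test_single_record_echo(self):
        hs = hs_frame([("c1", 0, 85_000, EU)])
        s = summarize(hs)
        pooled = s[(s["population"] == "all") & (s["chromatin"] == "all")].iloc[0]
        assert pooled["count"] == 1
        assert pooled["median_size_bp"] == 85_000

    def test_constant_sizes(self):
        hs = hs_frame([("c1", 0, 85_000, EU)] * 3)
        row = summarize(hs).iloc[0]
        assert row["mean_size_bp"] == row["median_size_bp"] == 85_000

    def test_counts_partition_by_class(self):
        hs = hs_frame([("c1", 0, 10_000, EU)] * 4 + [("c1", 0, 20_000, HET)] * 2)
        s = summarize(hs)
        eu = s[(s["chromatin"] == EU) & (s["population"] == "p")].iloc[0]
        het = s[(s["chromatin"] == HET) & (s["population"] == "p")].iloc[0]
        assert eu["count"] + het["count"] == 6


class TestSimulatedRecovery:
    def test_two_plateaus_recovered(self, two_hotspot_landscape,
                                    chromatin_map_c1):
        # planted at 4 Mbp and 16 Mbp (width 200 kb); >= 18/20 seeds must
        # recover both with peak within a half-width
        successes = 0
        for seed in range(20):
            gm, _ = simulate_ril_population(
                two_hotspot_landscape,
                default_marker_grid(two_hotspot_landscape, 25_000),
                n_lines=1000, rng=1000 + seed,
            )
            gm2, _ = run_qc(gm)
            marey = isotonize(MareyMap.from_genetic_map(build_map(gm2)))
            prof = rate_profile(fit_spline(marey, 0.1), 10_000)
            hs = call_hotspots(prof, chromatin_map_c1, window=5, min_fold=2.0)
            peaks = hs["peak"].to_numpy()
            ok = (np.any(np.abs(peaks - 4e6) <= 100_000)
                  and np.any(np.abs(peaks - 16e6) <= 100_000))
            successes += ok
        assert successes >= 18

    def test_power_increases_with_fold(self, chromatin_map_c1):
        detections = []
        for fold in (2, 5, 10):
            hits = 0
            for seed in range(8):
                ls = make_landscape(
                    [("c1", 10_000_000)], None,
                    [("c1", 5_000_000, 200_000, 5.0 * fold)],
                    {EU: 5.0},
                )
                gm, _ = simulate_ril_population(
                    ls, default_marker_grid(ls, 25_000), n_lines=500,
                    rng=seed * 13 + fold,
                )
                gm2, _ = run_qc(gm)
                marey = isotonize(MareyMap.from_genetic_map(build_map(gm2)))
                prof = rate_profile(fit_spline(marey, 0.1), 10_000)
                hs = call_hotspots(prof, window=5, min_fold=2.0)
                hits += bool(len(hs) and
                             np.any(np.abs(hs["peak"] - 5e6) <= 100_000))
            detections.append(hits)
        assert detections[0] <= detections[1] <= detections[2]
        assert detections[2] >= 7
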