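"""Simulator: landscape construction, meiosis, SSD population properties."""

import numpy as np
import pytest
from scipy import stats

from recmap.genotypes import GenotypeMatrix
from recmap.linkmap import correct_ril
from recmap.simulate import (
    DistortionLocus,
    HotspotSpec,
    default_marker_grid,
    founder_haplotype,
    make_landscape,
    simulate_meiosis,
    simulate_ril_population,
)

EU = "euchromatic"
HET = "heterochromatic"


class TestMakeLandscape:
    def test_uniform_total_map_length(self):
        ls = make_landscape([("c1", 50_000_000)], None, [], {EU: 5.0})
        assert ls.total_cM("c1") == pytest.approx(250.0)

    def test_plateau_only_integral(self):
        ls = make_landscape(
            [("c1", 10_000_000)], None,
            [("c1", 5_000_000, 100_000, 10.0)], {EU: 0.0},
        )
        assert ls.total_cM("c1") == pytest.approx(1.0)

    def test_two_class_total(self):
        # 10 Mbp at 1 cM/197 kb plus 10 Mbp at 1 cM/3.5 Mb
        chromatin = {"c1": [(0, 10e6, EU), (10e6, 20e6, HET)]}
        ls = make_landscape(
            [("c1", 20_000_000)], chromatin, [],
            {EU: 1.0 / 0.197, HET: 1.0 / 3.5},
        )
        assert ls.total_cM("c1") == pytest.approx(10 / 0.197 + 10 / 3.5, rel=1e-12)
        assert round(ls.total_cM("c1"), 1) == 53.6

    def test_cumulative_map_monotone_and_exact(self):
        ls = make_landscape(
            [("c1", 10_000_000)], {"c1": [(0, 6e6, EU), (6e6, 10e6, HET)]},
            [("c1", 3_000_000, 200_000, 20.0)], {EU: 4.0, HET: 0.5},
        )
        x = np.linspace(0, 10_000_000, 1001)
        cm = ls.map_cM("c1", x)
        assert np.all(np.diff(cm) >= 0)
        expected = 5.8 * 4.0 + 4.0 * 0.5 + 0.2 * 20.0
        assert ls.total_cM("c1") == pytest.approx(expected)

    def test_rejects_hotspot_outside_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            make_landscape([("c1", 1_000_000)], None,
                           [("c1", 990_000, 100_000, 5.0)], {EU: 1.0})

    def test_rejects_overlapping_hotspots(self):
        with pytest.raises(ValueError, match="[Oo]verlap"):
            make_landscape(
                [("c1", 10_000_000)], None,
                [("c1", 5_000_000, 200_000, 5.0), ("c1", 5_100_000, 200_000, 5.0)],
                {EU: 1.0},
            )

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            make_landscape([("c1", 1_000_000)], None, [], {EU: -1.0})

    def test_rate_function_values(self):
        ls = make_landscape([("c1", 10_000_000)], None,
                            [("c1", 5_000_000, 200_000, 30.0)], {EU: 2.0})
        assert float(ls.rate("c1", 1_000_000)) == 2.0
        assert float(ls.rate("c1", 5_000_000)) == 30.0


class TestMeiosis:
    def test_zero_rate_no_crossovers(self, rng):
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: 0.0})
        pair = (founder_haplotype(ls, 0), founder_haplotype(ls, 1))
        gamete, xovers = simulate_meiosis(pair, ls, rng)
        assert xovers == []
        breaks, origins = gamete["c1"]
        assert len(breaks) == 0 and origins[0] in (0, 1)

    def test_poisson_crossover_count(self, rng):
        # 100-cM chromosome: mean crossover count 1 Morgan (scaled-down n)
        ls = make_landscape([("c1", 10_000_000)], None, [], {EU: 10.0})
        pair = (founder_haplotype(ls, 0), founder_haplotype(ls, 1))
        n = 20_000
        counts = np.empty(n)
        for k in range(n):
            _, xovers = simulate_meiosis(pair, ls, rng)
            counts[k] = len(xovers)
        se = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - 1.0) < 3 * se

    def test_uniform_positions_ks(self, rng):
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: 200.0})
        pair = (founder_haplotype(ls, 0), founder_haplotype(ls, 1))
        positions = []
        while len(positions) < 10_000:
            _, xovers = simulate_meiosis(pair, ls, rng)
            positions.extend(p for _, p in xovers)
        u = np.array(positions[:10_000]) / 1_000_000
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_gamete_is_valid_mosaic(self, rng):
        ls = make_landscape([("c1", 10_000_000)], None, [], {EU: 20.0})
        pair = (founder_haplotype(ls, 0), founder_haplotype(ls, 1))
        gamete, xovers = simulate_meiosis(pair, ls, rng)
        breaks, origins = gamete["c1"]
        assert np.all(np.diff(breaks) > 0)
        assert len(origins) == len(breaks) + 1
        assert np.all(np.diff(origins) != 0)  # runs merged
        assert np.all((breaks > 0) & (breaks < 10_000_000))


class TestRILPopulation:
    def test_f5_heterozygote_frequency(self):
        # E[P(H)] at F5 = (1/2)^4 = 6.25%
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: 1.0})
        gm, _ = simulate_ril_population(
            ls, [("m1", "c1", 500_000)], n_lines=10_000, rng=5,
        )
        frac_h = (gm.calls == "H").mean()
        se = np.sqrt(0.0625 * 0.9375 / 10_000)
        assert abs(frac_h - 0.0625) < 3 * se

    def test_zero_rate_lines_nonrecombinant(self):
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: 0.0})
        markers = [("m1", "c1", 100_000), ("m2", "c1", 900_000)]
        gm, truth = simulate_ril_population(ls, markers, n_lines=200, rng=3)
        assert len(truth.crossover_records) == 0
        hom = (gm.calls != "H").all(axis=0)
        two_locus = {"".join(gm.calls[:, j]) for j in np.flatnonzero(hom)}
        assert two_locus <= {"AA", "BB"}  # parental combinations only

    def test_haldane_waddington_limit(self):
        # meiotic r = 0.1 between the two markers; at F-infinity the
        # recombinant-line fraction R -> 2r/(1+2r) = 1/6
        rate = -50.0 * np.log(0.8)  # Haldane: 11.157 cM over 1 Mbp -> r=0.1
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: rate})
        markers = [("m1", "c1", 0), ("m2", "c1", 999_999)]
        n = 3000
        gm, _ = simulate_ril_population(ls, markers, n_lines=n,
                                        final_generation=26, rng=11)
        a, b = gm.calls[0], gm.calls[1]
        hom = np.isin(a, ["A", "B"]) & np.isin(b, ["A", "B"])
        R = (a[hom] != b[hom]).mean()
        expect = 2 * 0.1 / (1 + 2 * 0.1)
        se = np.sqrt(expect * (1 - expect) / hom.sum())
        assert abs(R - expect) < 3 * se
        # and the Haldane-Waddington correction recovers r
        assert correct_ril(expect) == pytest.approx(0.1, rel=1e-12)

    def test_allele_symmetry_without_distortion(self, sim_population):
        gm, _ = sim_population
        fA = (gm.calls == "A").mean()
        fB = (gm.calls == "B").mean()
        # binomial sampling error at the number of lines (calls within a
        # line are correlated, so lines is the effective n)
        se = np.sqrt(0.5 * 0.5 / gm.n_lines)
        assert abs(fA - fB) < 6 * se

    def test_conservation_of_genotype_classes(self, sim_population):
        gm, _ = sim_population
        total = ((gm.calls == "A") | (gm.calls == "B") | (gm.calls == "H")).mean()
        assert total == 1.0  # no missing injected in this fixture

    def test_distortion_skews_allele_frequency(self):
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: 1.0})
        spec = [DistortionLocus("c1", 500_000, favored=0, weight=0.2)]
        gm, _ = simulate_ril_population(
            ls, [("m1", "c1", 500_000)], n_lines=2000,
            distortion_spec=spec, rng=7,
        )
        nA = (gm.calls == "A").sum()
        nB = (gm.calls == "B").sum()
        assert nA > 1.5 * nB

    def test_missingness_injection(self):
        ls = make_landscape([("c1", 1_000_000)], None, [], {EU: 1.0})
        markers = [(f"m{k}", "c1", 100_000 + 50_000 * k) for k in range(10)]
        gm, _ = simulate_ril_population(
            ls, markers, n_lines=500, missing_rate=0.2, rng=9,
        )
        frac = (gm.calls == "-").mean()
        assert 0.15 < frac < 0.25

    def test_reproducibility_same_seed(self, two_hotspot_landscape):
        markers = default_marker_grid(two_hotspot_landscape, 1_000_000)
        a, _ = simulate_ril_population(two_hotspot_landscape, markers, 50, rng=42)
        b, _ = simulate_ril_population(two_hotspot_landscape, markers, 50, rng=42)
        assert a.calls.tobytes() == b.calls.tobytes()
        assert a.markers.equals(b.markers)

    def test_marker_outside_chromosome_rejected(self, two_hotspot_landscape):
        with pytest.raises(ValueError, match="outside"):
            simulate_ril_population(
                two_hotspot_landscape, [("m1", "c1", 30_000_000)], 10, rng=0
            )

    def test_final_generation_validation(self, two_hotspot_landscape):
        with pytest.raises(ValueError):
            simulate_ril_population(
                two_hotspot_landscape, [("m1", "c1", 1000)], 10,
                final_generation=1, rng=0,
            )

    def test_truth_crossovers_in_bounds(self, sim_population):
        _, truth = sim_population
        pos = truth.crossover_records["position"].to_numpy()
        assert ((pos >= 0) & (pos <= 20_000_000)).all()
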