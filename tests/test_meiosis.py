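import math
import warnings

import numpy as np
import pytest

from juxtarec.meiosis import (
    CrossDesign,
    Gamete,
    JuxtapositionModel,
    RecombinationLandscape,
    Scenario,
    SimulationError,
    ZygosityMap,
    default_scenario,
    map_length,
    remodel_landscape,
    sample_gamete,
    simulate_cross,
    simulate_experiment,
)
from juxtarec.rf_estimators import BackcrossCounts, F2PhenotypeCounts, SeedCounts

from conftest import random_landscape, random_zygosity

MB = 1_000_000


class TestLandscape:
    def test_tiling_enforced(self):
        with pytest.raises(SimulationError):
            RecombinationLandscape(100, ((0, 40, 1.0), (50, 100, 1.0)))
        with pytest.raises(SimulationError):
            RecombinationLandscape(100, ((0, 60, 1.0), (40, 100, 1.0)))

    def test_total_map_length(self):
        lsc = RecombinationLandscape(2 * MB, ((0, MB, 1.0), (MB, 2 * MB, 3.0)))
        assert lsc.total_map_cm == pytest.approx(4.0, abs=1e-9)

    def test_map_length_empty_range(self, uniform_landscape):
        assert map_length(uniform_landscape, 5 * MB, 5 * MB) == 0.0

    def test_map_length_whole_chromosome(self, uniform_landscape):
        assert map_length(uniform_landscape, 0, 100 * MB) == pytest.approx(
            uniform_landscape.total_map_cm, abs=1e-12
        )

    def test_map_length_additive_at_midpoint(self, rng):
        for _ in range(20):
            lsc = random_landscape(rng)
            lo, hi = sorted(rng.integers(0, lsc.chrom_length, size=2))
            mid = (lo + hi) // 2
            whole = map_length(lsc, lo, hi)
            split = map_length(lsc, lo, mid) + map_length(lsc, mid, hi)
            assert split == pytest.approx(whole, abs=1e-12)

    def test_reversed_range_rejected(self, uniform_landscape):
        with pytest.raises(SimulationError):
            map_length(uniform_landscape, 10, 5)


class TestZygosityMap:
    def test_adjacent_same_state_merged(self):
        zyg = ZygosityMap(100, ((0, 40, "HOM"), (40, 60, "HOM"), (60, 100, "HET")))
        assert zyg.segments == ((0, 60, "HOM"), (60, 100, "HET"))

    def test_from_het_intervals(self):
        zyg = ZygosityMap.from_het_intervals(100, [(10, 20), (50, 60)])
        states = [s for _, _, s in zyg.segments]
        assert states == ["HOM", "HET", "HOM", "HET", "HOM"]


class TestRemodel:
    def test_zero_strength_is_identity(self, uniform_landscape, juxtaposed_zygosity):
        model = JuxtapositionModel(strength=0.0)
        out = remodel_landscape(uniform_landscape, juxtaposed_zygosity, model)
        assert out is uniform_landscape

    def test_fully_het_unchanged(self, uniform_landscape):
        hybrid = ZygosityMap(100 * MB, ((0, 100 * MB, "HET"),))
        out = remodel_landscape(uniform_landscape, hybrid, JuxtapositionModel())
        assert out is uniform_landscape

    def test_fully_hom_unchanged(self, uniform_landscape):
        inbred = ZygosityMap(100 * MB, ((0, 100 * MB, "HOM"),))
        out = remodel_landscape(uniform_landscape, inbred, JuxtapositionModel())
        assert out is uniform_landscape

    def test_het_interval_gains_total_conserved(self, uniform_landscape,
                                                juxtaposed_zygosity):
        model = JuxtapositionModel(strength=2.0, decay_cm=20.0)
        out = remodel_landscape(uniform_landscape, juxtaposed_zygosity, model)
        before = map_length(uniform_landscape, 45 * MB, 55 * MB)
        after = map_length(out, 45 * MB, 55 * MB)
        assert after > before
        assert out.total_map_cm == pytest.approx(
            uniform_landscape.total_map_cm, rel=1e-9
        )

    def test_conservation_over_random_triples(self, rng):
        checked = 0
        for _ in range(200):
            lsc = random_landscape(rng)
            zyg = random_zygosity(rng, lsc.chrom_length)
            model = JuxtapositionModel(
                strength=float(rng.uniform(0.1, 4.0)),
                decay_cm=float(rng.uniform(1.0, 30.0)),
                activity_threshold=float(rng.uniform(0.0, 1.0)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = remodel_landscape(lsc, zyg, model, resolution_bp=250_000)
            assert np.all(out.rates >= 0.0)
            tol = max(1e-9, 1e-9 * lsc.total_map_cm)
            assert abs(out.total_map_cm - lsc.total_map_cm) <= tol
            checked += 1
        assert checked == 200

    def test_inactive_flank_contributes_nothing(self):
        # HOM side entirely below the activity threshold within delta:
        # no boundary is active and the landscape is returned unchanged
        length = 100 * MB
        base = RecombinationLandscape(
            length, ((0, 45 * MB, 0.1), (45 * MB, length, 1.0))
        )
        zyg = ZygosityMap(length, ((0, 45 * MB, "HOM"), (45 * MB, length, "HET")))
        model = JuxtapositionModel(strength=2.0, decay_cm=10.0, activity_threshold=0.5)
        out = remodel_landscape(base, zyg, model)
        assert out is base

    def test_stimulation_decays_with_distance(self, uniform_landscape):
        # unit HET windows at increasing distance from a single boundary
        model = JuxtapositionModel(strength=2.0, decay_cm=15.0)
        zyg = ZygosityMap(100 * MB, ((0, 50 * MB, "HOM"), (50 * MB, 100 * MB, "HET")))
        out = remodel_landscape(uniform_landscape, zyg, model)
        gains = []
        for start in range(50, 95, 5):
            before = map_length(uniform_landscape, start * MB, (start + 5) * MB)
            after = map_length(out, start * MB, (start + 5) * MB)
            gains.append(after - before)
        assert all(g1 > g2 for g1, g2 in zip(gains, gains[1:]))
        assert gains[-1] > -1e-12

    def test_insufficient_donors_scaled_with_warning(self):
        length = 100 * MB
        base = RecombinationLandscape.uniform(length, 1.0)
        # tiny HOM island cannot fund stimulation of the huge HET remainder
        zyg = ZygosityMap(
            length, ((0, 49 * MB, "HET"), (49 * MB, 51 * MB, "HOM"),
                     (51 * MB, length, "HET"))
        )
        model = JuxtapositionModel(strength=3.0, decay_cm=30.0)
        with pytest.warns(UserWarning, match="insufficient donor"):
            out = remodel_landscape(base, zyg, model)
        assert np.all(out.rates >= 0.0)
        assert out.total_map_cm == pytest.approx(base.total_map_cm, rel=1e-9)

    def test_mismatched_chromosomes_rejected(self, uniform_landscape):
        zyg = ZygosityMap(50 * MB, ((0, 50 * MB, "HET"),))
        with pytest.raises(SimulationError):
            remodel_landscape(uniform_landscape, zyg, JuxtapositionModel())


class TestGameteSampling:
    def test_zero_rate_landscape_never_recombines(self, rng):
        lsc = RecombinationLandscape.uniform(MB, 0.0)
        for _ in range(20):
            assert sample_gamete(lsc, rng).breakpoints == ()

    def test_breakpoints_sorted_and_inside(self, rng):
        lsc = RecombinationLandscape.uniform(10 * MB, 30.0)  # 3 Morgans
        for _ in range(200):
            gam = sample_gamete(lsc, rng)
            bps = np.array(gam.breakpoints)
            assert np.all(np.diff(bps) > 0)
            if bps.size:
                assert bps[0] > 0 and bps[-1] < lsc.chrom_length

    def test_poisson_mean_matches_map_length(self, rng):
        lsc = RecombinationLandscape(
            10 * MB, ((0, 2 * MB, 5.0), (2 * MB, 10 * MB, 10.0))
        )  # 0.9 Morgans
        n = 100_000
        from juxtarec.meiosis import _sample_breakpoint_sets

        _, counts = _sample_breakpoint_sets(lsc, n, rng)
        se = math.sqrt(lsc.total_map_morgans / n)
        assert abs(counts.mean() - lsc.total_map_morgans) <= 3 * se

    def test_positions_follow_rate_density(self, rng):
        lsc = RecombinationLandscape(10 * MB, ((0, 5 * MB, 1.0), (5 * MB, 10 * MB, 4.0)))
        from juxtarec.meiosis import _sample_breakpoint_sets

        positions, _ = _sample_breakpoint_sets(lsc, 50_000, rng)
        frac_right = np.mean(positions >= 5 * MB)
        assert frac_right == pytest.approx(0.8, abs=0.01)

    def test_obligate_crossover(self, rng):
        lsc = RecombinationLandscape.uniform(MB, 10.0)  # 0.1 Morgans
        for _ in range(50):
            gam = sample_gamete(lsc, rng, obligate_co=True)
            assert len(gam.breakpoints) >= 1

    def test_obligate_on_zero_map_rejected(self, rng):
        lsc = RecombinationLandscape.uniform(MB, 0.0)
        with pytest.raises(SimulationError):
            sample_gamete(lsc, rng, obligate_co=True)

    def test_gamete_invariants(self):
        with pytest.raises(SimulationError):
            Gamete((5.0, 5.0), 0)
        with pytest.raises(SimulationError):
            Gamete((1.0,), 2)
        assert Gamete((1.0, 2.0), 0).phase_at(1.5) == 1


class TestSimulateCross:
    def test_zero_distance_markers_never_recombinant(self, rng):
        lsc = RecombinationLandscape(
            100 * MB,
            ((0, 40 * MB, 1.0), (40 * MB, 60 * MB, 0.0), (60 * MB, 100 * MB, 1.0)),
        )
        design = CrossDesign("backcross", 45 * MB, 55 * MB)
        counts = simulate_cross(design, lsc, 5000, rng)
        assert counts.b + counts.c == 0

    def test_backcross_matches_haldane(self):
        # uniform landscape, markers 0.10 M apart, 200k gametes
        lsc = RecombinationLandscape.uniform(100 * MB, 1.0)
        design = CrossDesign("backcross", 20 * MB, 30 * MB)
        counts = simulate_cross(design, lsc, 200_000, seed=77)
        expected = (1.0 - math.exp(-0.2)) / 2.0
        se = math.sqrt(expected * (1 - expected) / 200_000)
        assert abs((counts.b + counts.c) / counts.n - expected) <= 3 * se

    def test_f2_counts_conserved(self, rng):
        lsc = RecombinationLandscape.uniform(50 * MB, 2.0)
        design = CrossDesign("f2", 10 * MB, 30 * MB)
        counts = simulate_cross(design, lsc, 1234, rng)
        assert isinstance(counts, F2PhenotypeCounts)
        assert counts.a + counts.b + counts.c + counts.d == 1234

    def test_f2_class_frequencies(self):
        lsc = RecombinationLandscape.uniform(100 * MB, 1.0)
        design = CrossDesign("f2", 20 * MB, 30 * MB)  # 10 cM
        counts = simulate_cross(design, lsc, 100_000, seed=5)
        x = (1.0 - math.exp(-0.2)) / 2.0
        theta = (1 - x) ** 2
        n = counts.n
        for observed, p in [(counts.a, (2 + theta) / 4), (counts.b, (1 - theta) / 4),
                            (counts.c, (1 - theta) / 4), (counts.d, theta / 4)]:
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed / n - p) <= 4 * se

    def test_seed_fluorescence_single_colour_fraction(self):
        lsc = RecombinationLandscape.uniform(100 * MB, 1.0)
        design = CrossDesign("seed_fluorescence", 20 * MB, 30 * MB)
        counts = simulate_cross(design, lsc, 200_000, seed=11)
        assert isinstance(counts, SeedCounts)
        x = (1.0 - math.exp(-0.2)) / 2.0
        expected = x - x * x / 2.0
        se = math.sqrt(expected * (1 - expected) / counts.n)
        assert abs(counts.single_colour_fraction - expected) <= 3 * se

    def test_markers_outside_rejected(self, rng, uniform_landscape):
        with pytest.raises(SimulationError):
            simulate_cross(CrossDesign("backcross", 0, 200 * MB),
                           uniform_landscape, 10, rng)

    def test_estimator_recovery_unbiased(self):
        # backcross estimator on simulator output vs Haldane transform, n=1e5
        lsc = RecombinationLandscape.uniform(100 * MB, 1.0)
        d_cm = map_length(lsc, 40 * MB, 55 * MB)
        design = CrossDesign("backcross", 40 * MB, 55 * MB)
        counts = simulate_cross(design, lsc, 100_000, seed=13)
        expected = (1.0 - math.exp(-2 * d_cm / 100.0)) / 2.0
        se = math.sqrt(expected * (1 - expected) / 100_000)
        from juxtarec.rf_estimators import rf_from_backcross

        assert abs(rf_from_backcross(counts).rf - expected) <= 3 * se


@pytest.fixture(scope="module")
def result():
    scenario = default_scenario(seed=7, plants_per_config=6, progeny_per_plant=400)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_experiment(scenario)


class TestSimulateExperiment:
    def test_all_configurations_present(self, result):
        assert set(result["configuration"]) == {
            "inbred", "hybrid", "juxtaposed", "reverse_juxtaposed",
            "interrupted_juxtaposed",
        }
        assert (result.groupby("configuration").size() == 6).all()

    def test_juxtaposed_exceeds_hybrid(self, result):
        means = result.groupby("configuration")["rf"].mean()
        assert means["juxtaposed"] > means["hybrid"]
        assert means["reverse_juxtaposed"] < means["inbred"]

    def test_zero_strength_indistinguishable(self):
        scenario = default_scenario(seed=3, strength=0.0, plants_per_config=6,
                                    progeny_per_plant=400)
        df = simulate_experiment(scenario)
        cm = df.groupby("configuration")["interval_cm"].first()
        assert cm.nunique() == 1  # identical landscapes in every configuration

    def test_interval_gain_monotone_in_strength(self):
        cms = []
        for s in (0.0, 0.5, 1.0, 2.0, 3.0):
            scenario = default_scenario(seed=1, strength=s, plants_per_config=1,
                                        progeny_per_plant=10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = simulate_experiment(scenario)
            jux = df[df["configuration"] == "juxtaposed"]
            cms.append(float(jux["interval_cm"].iloc[0]))
        assert all(b >= a - 1e-12 for a, b in zip(cms, cms[1:]))

    def test_calibrated_ratio_two_to_three(self, result):
        means = result.groupby("configuration")["rf"].mean()
        ratio = means["juxtaposed"] / means["hybrid"]
        assert 1.8 <= ratio <= 3.2  # defaults calibrated near the observed 2-3x

    def test_unknown_configuration_estimator(self):
        with pytest.raises(SimulationError):
            CrossDesign("tetrad", 0, 10)
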