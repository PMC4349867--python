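"""Synthetic-data generator: marker maps, event planting, ratio simulation."""

import numpy as np
import pandas as pd
import pytest

from lohmap.genome import GenomeModel, MarkerMap
from lohmap.simulate import (
    NoiseModel,
    PlantedEvent,
    SimulationConfig,
    build_marker_map,
    plan_colony_events,
    plant_events,
    simulate_colonies,
    simulate_ratios,
)


class TestBuildMarkerMap:
    def test_marker_count_and_chromosome_coverage(self, genome, markers):
        assert len(markers) == 13000
        assert set(markers.chroms) == set(genome.names)

    def test_exhaustive_placement_on_tiny_chromosome(self):
        g = GenomeModel({"chr1": 1000})
        m = build_marker_map(g, 1000, seed=0)
        assert list(m.positions) == list(range(1, 1001))

    def test_same_seed_reproduces_bit_identical_map(self, genome):
        a = build_marker_map(genome, 2000, seed=42)
        b = build_marker_map(genome, 2000, seed=42)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_different_seeds_differ_but_positions_sorted(self, genome):
        a = build_marker_map(genome, 2000, seed=1)
        b = build_marker_map(genome, 2000, seed=2)
        assert not a.df["pos"].equals(b.df["pos"])
        for m in (a, b):
            for chrom in genome.names:
                pos = m.chrom_positions(chrom)
                assert (np.diff(pos) > 0).all()

    def test_allocation_roughly_proportional_to_length(self, genome, markers):
        counts = markers.df["chrom"].value_counts()
        total = genome.total_length
        for chrom, length in genome.lengths.items():
            expect = 13000 * length / total
            sd = np.sqrt(expect)
            assert abs(counts[chrom] - expect) < 6 * sd

    def test_oversized_request_rejected(self):
        g = GenomeModel({"chr1": 100})
        with pytest.raises(ValueError, match="cannot place"):
            build_marker_map(g, 101, seed=0)

    def test_fewer_markers_than_chromosomes_rejected(self, genome):
        with pytest.raises(ValueError):
            build_marker_map(genome, 10, seed=0)


class TestPlantEvents:
    def test_no_events_gives_all_het_disomic(self, tiny_markers):
        truth, events = plant_events(tiny_markers, [])
        assert events == []
        for sector in ("D1", "D2"):
            assert (truth.states(sector) == "HET").all()
            assert all(c == 2 for c in truth.chrom_copy[sector].values())

    def test_simple_crossover_identical_transition_opposite_haplotypes(
        self, tiny_markers
    ):
        c = 600_000
        ev = PlantedEvent("CO_SIMPLE", "chr1", c, c, donor="W")
        truth, _ = plant_events(tiny_markers, [ev])
        pos = tiny_markers.chrom_positions("chr1")
        sl = tiny_markers.chrom_slice("chr1")
        d1 = truth.states("D1")[sl]
        d2 = truth.states("D2")[sl]
        assert (d1[pos > c] == "HOM_W").all()
        assert (d2[pos > c] == "HOM_Y").all()
        assert (d1[pos <= c] == "HET").all()
        assert (d2[pos <= c] == "HET").all()

    def test_bir_terminal_affects_exactly_one_sector(self, tiny_markers):
        ev = PlantedEvent("BIR_TERMINAL", "chr1", 800_000, 1_000_000, donor="W")
        truth, _ = plant_events(tiny_markers, [ev])
        pos = tiny_markers.chrom_positions("chr1")
        sl = tiny_markers.chrom_slice("chr1")
        d1 = truth.states("D1")[sl]
        assert (d1[pos >= 800_000] == "HOM_W").all()
        assert (d1[pos < 800_000] == "HET").all()
        assert (truth.states("D2") == "HET").all()

    def test_crossover_reciprocity_distal_haplotypes(self, tiny_markers):
        """Distal to any planted crossover the two sectors are homozygous
        for complementary haplotypes."""
        for cls in ("CO_SIMPLE", "CO_3TO1", "CO_4TO0", "CO_HYBRID"):
            for donor in ("W", "Y"):
                ev = PlantedEvent(cls, "chr1", 500_000, 540_000, donor=donor)
                truth, _ = plant_events(tiny_markers, [ev])
                pos = tiny_markers.chrom_positions("chr1")
                sl = tiny_markers.chrom_slice("chr1")
                distal = pos > 540_000
                d1 = truth.states("D1")[sl][distal]
                d2 = truth.states("D2")[sl][distal]
                other = "Y" if donor == "W" else "W"
                assert (d1 == f"HOM_{donor}").all()
                assert (d2 == f"HOM_{other}").all()

    def test_conversion_tract_counts_three_to_one_vs_four_to_zero(
        self, tiny_markers
    ):
        """Across the four chromatids of both daughters, a 3:1 tract carries
        three donor copies and a 4:0 tract four."""
        tract = (500_000, 540_000)
        for cls, expected in (("CO_3TO1", 3), ("CO_4TO0", 4)):
            ev = PlantedEvent(cls, "chr1", *tract, donor="W")
            truth, _ = plant_events(tiny_markers, [ev])
            pos = tiny_markers.positions
            in_tract = (
                (tiny_markers.chroms == "chr1")
                & (pos >= tract[0])
                & (pos <= tract[1])
            )
            donor_copies = (
                truth.w_copies["D1"][in_tract] + truth.w_copies["D2"][in_tract]
            )
            assert (donor_copies == expected).all()

    def test_deletion_is_hemizygous_for_retained_haplotype(self, tiny_markers):
        ev = PlantedEvent("DELETION", "chr1", 300_000, 320_000, donor="Y")
        truth, _ = plant_events(tiny_markers, [ev])
        pos = tiny_markers.positions
        in_tract = (
            (tiny_markers.chroms == "chr1") & (pos >= 300_000) & (pos <= 320_000)
        )
        assert (truth.states("D1")[in_tract] == "DEL_W").all()

    def test_overlapping_tracts_rejected(self, tiny_markers):
        evs = [
            PlantedEvent("NCO_INTERSTITIAL", "chr1", 300_000, 320_000),
            PlantedEvent("NCO_INTERSTITIAL", "chr1", 310_000, 330_000),
        ]
        with pytest.raises(ValueError, match="overlap"):
            plant_events(tiny_markers, evs)

    def test_markerless_tract_warns_but_is_retained(self, tiny_markers):
        pos = tiny_markers.chrom_positions("chr1")
        gaps = np.diff(pos)
        i = int(np.argmax(gaps))
        lo, hi = int(pos[i]) + 1, int(pos[i + 1]) - 1
        assert hi > lo
        ev = PlantedEvent("NCO_INTERSTITIAL", "chr1", lo, hi)
        with pytest.warns(UserWarning, match="no markers"):
            truth, events = plant_events(tiny_markers, [ev])
        assert events == [ev]
        assert (truth.states("D1") == "HET").all()

    def test_break_type_implied_by_class(self):
        assert PlantedEvent("CO_3TO1", "chr1", 1, 2).break_type == "SCB"
        assert PlantedEvent("CO_4TO0", "chr1", 1, 2).break_type == "DSCB"
        assert PlantedEvent("CO_HYBRID", "chr1", 1, 2).break_type == "DSCB"
        assert PlantedEvent("CO_SIMPLE", "chr1", 1, 1).break_type == "NA"
        with pytest.raises(ValueError, match="implies break type"):
            PlantedEvent("CO_3TO1", "chr1", 1, 2, break_type="DSCB")


class TestSimulateRatios:
    def test_noiseless_channel_means(self, tiny_markers):
        truth, _ = plant_events(
            tiny_markers,
            [PlantedEvent("NCO_INTERSTITIAL", "chr1", 300_000, 400_000, donor="W")],
        )
        ratios = simulate_ratios(truth, tiny_markers, NoiseModel(sigma=0.0), seed=0)
        d1 = ratios["D1"]
        hom = truth.states("D1") == "HOM_W"
        het = truth.states("D1") == "HET"
        assert (d1.loc[het, "ratio_W"] == 1.0).all()
        assert (d1.loc[het, "ratio_Y"] == 1.0).all()
        assert (d1.loc[hom, "ratio_W"] == 1.8).all()
        assert (d1.loc[hom, "ratio_Y"] == 0.2).all()

    def test_lognormal_noise_centred_on_zero_log_mean(self, markers):
        truth, _ = plant_events(markers, [])
        ratios = simulate_ratios(markers=markers, truth=truth,
                                 noise=NoiseModel(sigma=0.1), seed=5)
        logs = np.log(ratios["D1"]["ratio_W"].to_numpy())
        n = len(logs)
        se = 0.1 / np.sqrt(n)
        assert abs(logs.mean()) < 3 * se

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            NoiseModel(sigma=-0.1)

    def test_mean_ordering_enforced(self):
        with pytest.raises(ValueError, match="channel means"):
            NoiseModel(mean_copy1=2.0)


class TestColonySimulation:
    def test_same_seed_bit_identical(self, tiny_markers):
        cfg = SimulationConfig(mean_events=3.0)
        a = simulate_colonies(tiny_markers, 3, cfg, seed=9)
        b = simulate_colonies(tiny_markers, 3, cfg, seed=9)
        for ca, cb in zip(a, b):
            assert ca.events == cb.events
            for s in ("D1", "D2"):
                pd.testing.assert_frame_equal(ca.ratios[s], cb.ratios[s])

    def test_rate_mode_event_count_near_poisson_mean(self, markers):
        cfg = SimulationConfig(mean_events=7.1)
        cols = simulate_colonies(markers, 40, cfg, seed=13)
        counts = [len(c.events) for c in cols]
        mean = np.mean(counts)
        # Poisson(7.1) mean over 40 colonies, truncated by arm availability
        assert 5.5 < mean < 8.5

    def test_planted_tracts_span_min_markers(self, markers):
        cfg = SimulationConfig(mean_events=7.1)
        cols = simulate_colonies(markers, 20, cfg, seed=17)
        for col in cols:
            for ev in col.events:
                if ev.event_class in ("CO_SIMPLE", "ANEUPLOIDY"):
                    continue
                pos = markers.chrom_positions(ev.chrom)
                n = np.sum((pos >= ev.tract_start) & (pos <= ev.tract_end))
                assert n >= cfg.min_tract_markers
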