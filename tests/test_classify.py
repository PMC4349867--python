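"""Event classification from paired-sector patterns."""

import numpy as np
import pytest

from lohmap.classify import (
    LOHEvent,
    assign_break_type,
    classify_colony,
    detect_aneuploidy,
    match_sectors,
    split_distant_events,
    summarize_colony,
)
from lohmap.pipeline import AnalysisParams, analyze_colony, evaluate_recovery
from lohmap.genotyping import segment_genome
from lohmap.simulate import (
    NoiseModel,
    PlantedEvent,
    SimulationConfig,
    plant_events,
    simulate_colonies,
    simulate_ratios,
)

ZERO_NOISE = SimulationConfig(noise=NoiseModel(sigma=0.0))


def _analyze_planted(markers, events, seed=0, sigma=0.0):
    cfg = SimulationConfig(noise=NoiseModel(sigma=sigma))
    truth, _ = plant_events(markers, events)
    ratios = simulate_ratios(truth, markers, cfg.noise, seed=seed)
    return analyze_colony(ratios, markers, colony="c0")


def _segments_for(markers, events, sector):
    truth, _ = plant_events(markers, events)
    return segment_genome(truth.states(sector), markers)


class TestMatchSectors:
    def test_all_het_single_joint_block(self, tiny_markers):
        d1 = _segments_for(tiny_markers, [], "D1")
        d2 = _segments_for(tiny_markers, [], "D2")
        aligned = match_sectors(d1, d2, tiny_markers)
        for chrom, blocks in aligned.items():
            assert len(blocks) == 1
            assert blocks[0][:2] == ("HET", "HET")

    def test_identical_breakpoint_two_blocks(self, tiny_markers):
        evs = [PlantedEvent("CO_SIMPLE", "chr1", 500_000, 500_000)]
        truth, _ = plant_events(tiny_markers, evs)
        d1 = segment_genome(truth.states("D1"), tiny_markers)
        d2 = segment_genome(truth.states("D2"), tiny_markers)
        blocks = match_sectors(d1, d2, tiny_markers)["chr1"]
        assert [b[:2] for b in blocks] == [("HET", "HET"), ("HOM_W", "HOM_Y")]

    def test_joint_blocks_are_breakpoint_union(self, tiny_markers):
        # D1 changes at the conversion-tract start, D2 at its end: the joint
        # pattern has three blocks from the union of the two breakpoints
        evs = [PlantedEvent("CO_3TO1", "chr1", 500_000, 540_000, donor="W")]
        truth, _ = plant_events(tiny_markers, evs)
        d1 = segment_genome(truth.states("D1"), tiny_markers)
        d2 = segment_genome(truth.states("D2"), tiny_markers)
        assert sum(s.chrom == "chr1" for s in d1) == 2
        assert sum(s.chrom == "chr1" for s in d2) == 2
        blocks = match_sectors(d1, d2, tiny_markers)["chr1"]
        assert [b[:2] for b in blocks] == [
            ("HET", "HET"), ("HOM_W", "HET"), ("HOM_W", "HOM_Y")
        ]


class TestClassifyPatterns:
    @pytest.mark.parametrize(
        "cls,kwargs",
        [
            ("CO_SIMPLE", dict(tract=(500_000, 500_000))),
            ("CO_3TO1", dict(tract=(500_000, 540_000))),
            ("CO_4TO0", dict(tract=(500_000, 540_000))),
            ("CO_HYBRID", dict(tract=(500_000, 560_000))),
            ("NCO_INTERSTITIAL", dict(tract=(300_000, 330_000))),
            ("BIR_TERMINAL", dict(tract=(700_000, 1_000_000))),
            ("DELETION", dict(tract=(300_000, 330_000))),
        ],
    )
    def test_each_pattern_recovers_its_class(self, tiny_markers, cls, kwargs):
        ev = PlantedEvent(cls, "chr1", *kwargs["tract"])
        events = _analyze_planted(tiny_markers, [ev])
        assert [e.event_class for e in events] == [cls]

    def test_left_arm_orientation_recovered(self, tiny_markers):
        ev = PlantedEvent("CO_3TO1", "chr1", 300_000, 340_000, side="L")
        events = _analyze_planted(tiny_markers, [ev])
        assert [e.event_class for e in events] == ["CO_3TO1"]

    def test_simple_crossover_break_type_unclassified(self, tiny_markers):
        ev = PlantedEvent("CO_SIMPLE", "chr1", 500_000, 500_000)
        (event,) = _analyze_planted(tiny_markers, [ev])
        assert event.break_type == "UNCLASSIFIED"

    def test_three_to_one_is_scb_and_hybrid_is_dscb(self, tiny_markers):
        for cls, bt in (("CO_3TO1", "SCB"), ("CO_4TO0", "DSCB"), ("CO_HYBRID", "DSCB")):
            tract = (500_000, 560_000)
            (event,) = _analyze_planted(
                tiny_markers, [PlantedEvent(cls, "chr1", *tract)]
            )
            assert (event.event_class, event.break_type) == (cls, bt)

    def test_bir_carries_second_division_caveat(self, tiny_markers):
        ev = PlantedEvent("BIR_TERMINAL", "chr1", 700_000, 1_000_000)
        (event,) = _analyze_planted(tiny_markers, [ev])
        assert "possible_second_division_crossover" in event.flags

    def test_monosomy_detected_chromosome_wide(self, tiny_markers):
        ev = PlantedEvent("ANEUPLOIDY", "chr2", 1, 500_000, donor="W", sector="D2")
        events = _analyze_planted(tiny_markers, [ev])
        anea = [e for e in events if e.event_class == "ANEUPLOIDY"]
        assert len(anea) == 1
        assert anea[0].chrom == "chr2" and anea[0].sector == "D2"

    def test_crossover_reciprocity_in_recovered_events(self, tiny_markers):
        """Every recovered crossover implies opposite distal haplotypes: at
        zero noise the distal joint block is (HOM_x, HOM_y), x != y."""
        ev = PlantedEvent("CO_3TO1", "chr1", 500_000, 540_000, donor="Y", sector="D2")
        truth, _ = plant_events(tiny_markers, [ev])
        d1 = truth.states("D1")
        d2 = truth.states("D2")
        sl = tiny_markers.chrom_slice("chr1")
        pos = tiny_markers.chrom_positions("chr1")
        distal = pos > 540_000
        assert set(d1[sl][distal]) == {"HOM_W"}
        assert set(d2[sl][distal]) == {"HOM_Y"}
        events = _analyze_planted(tiny_markers, [ev])
        assert [e.event_class for e in events] == ["CO_3TO1"]
        assert events[0].donor == "Y"


class TestSingleColonyMode:
    def test_terminal_loh_pooled_as_co_bir(self, tiny_markers):
        truth, _ = plant_events(
            tiny_markers,
            [PlantedEvent("BIR_TERMINAL", "chr1", 700_000, 1_000_000)],
        )
        segs = {"D1": segment_genome(truth.states("D1"), tiny_markers)}
        events = classify_colony(segs, tiny_markers, mode="SINGLE_COLONY")
        (event,) = events
        assert event.category == "CO_BIR"
        assert "co_bir_indistinguishable" in event.flags

    def test_interstitial_loh_stays_interstitial(self, tiny_markers):
        truth, _ = plant_events(
            tiny_markers,
            [PlantedEvent("NCO_INTERSTITIAL", "chr1", 300_000, 330_000)],
        )
        segs = {"D1": segment_genome(truth.states("D1"), tiny_markers)}
        (event,) = classify_colony(segs, tiny_markers, mode="SINGLE_COLONY")
        assert event.category == "INTERSTITIAL"


class TestSplitDistantEvents:
    def _nco(self, start, end, colony="c", chrom="chr1", sector="D1"):
        return LOHEvent(colony, "NCO_INTERSTITIAL", chrom, start, end, sector=sector)

    def test_distant_blocks_stay_two_events(self):
        evs = [self._nco(100_000, 105_000), self._nco(155_000, 160_000)]
        out = split_distant_events(evs, tract_median_kb=6.4, tract_mad_kb=3.0)
        assert len(out) == 2

    def test_close_blocks_merge_into_spanning_event(self):
        evs = [self._nco(100_000, 105_000), self._nco(107_000, 112_000)]
        out = split_distant_events(evs, tract_median_kb=6.4, tract_mad_kb=3.0)
        assert len(out) == 1
        assert (out[0].tract_start, out[0].tract_end) == (100_000, 112_000)
        assert "merged" in out[0].flags

    def test_event_count_monotone_in_threshold(self):
        """Raising the MAD (hence the merge threshold) never increases the
        event count, exhaustively over small block configurations."""
        for gaps in [(2, 2), (2, 20), (20, 2), (20, 20), (5, 13, 40)]:
            start = 100_000
            evs = []
            for g in (0,) + tuple(gaps):
                start += g * 1000
                evs.append(self._nco(start, start + 5000))
                start += 5000
            prev = None
            for mad in (0.0, 1.0, 3.0, 8.0, 20.0):
                out = split_distant_events(evs, 6.4, mad)
                if prev is not None:
                    assert len(out) <= prev
                prev = len(out)

    def test_different_sectors_never_merge(self):
        evs = [
            self._nco(100_000, 105_000, sector="D1"),
            self._nco(107_000, 112_000, sector="D2"),
        ]
        out = split_distant_events(evs, 6.4, 3.0)
        assert len(out) == 2

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            split_distant_events([], -1.0, 0.0)


class TestSummaries:
    def test_empty_colony_all_zeros(self):
        s = summarize_colony([], colony="c1")
        assert (s.interstitial, s.crossovers, s.bir, s.total_loh) == (0, 0, 0, 0)

    def test_category_tallies(self):
        evs = [
            LOHEvent("c", "CO_3TO1", "chr1", 1, 2),
            LOHEvent("c", "NCO_INTERSTITIAL", "chr2", 1, 2),
            LOHEvent("c", "BIR_TERMINAL", "chr3", 1, 2),
            LOHEvent("c", "DELETION", "chr4", 1, 2),
        ]
        s = summarize_colony(evs)
        assert (s.interstitial, s.crossovers, s.bir) == (1, 1, 1)
        assert s.total_loh == 3
        assert s.deletions == 1

    def test_selected_chromosome_excludable(self):
        evs = [
            LOHEvent("c", "CO_SIMPLE", "chrV", 1, 2),
            LOHEvent("c", "NCO_INTERSTITIAL", "chr2", 1, 2),
        ]
        s = summarize_colony(evs, exclude_chrom="chrV")
        assert s.crossovers == 0 and s.interstitial == 1


class TestAssignBreakType:
    @pytest.mark.parametrize(
        "cls,bt",
        [
            ("CO_3TO1", "SCB"),
            ("CO_4TO0", "DSCB"),
            ("CO_HYBRID", "DSCB"),
            ("CO_SIMPLE", "UNCLASSIFIED"),
            ("NCO_INTERSTITIAL", "NA"),
            ("BIR_TERMINAL", "NA"),
        ],
    )
    def test_mapping(self, cls, bt):
        ev = LOHEvent("c", cls, "chr1", 1, 2)
        assert assign_break_type(ev).break_type == bt


class TestDetectAneuploidy:
    def test_trisomy_called_from_ratio_means(self, tiny_markers):
        truth, _ = plant_events(
            tiny_markers,
            [
                PlantedEvent(
                    "ANEUPLOIDY", "chr2", 1, 500_000, donor="W", copy_number=3
                )
            ],
        )
        ratios = simulate_ratios(truth, tiny_markers, NoiseModel(sigma=0.1), seed=3)
        calls = detect_aneuploidy(ratios["D1"], tiny_markers)
        assert calls == {"chr2": 3}
        assert detect_aneuploidy(ratios["D2"], tiny_markers) == {}
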