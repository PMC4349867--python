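"""Synthetic-data generator: hybrid-diploid genomes with planted LOH events.

Models a diploid formed from two sequence-diverged haploids, W and Y, that is
heterozygous at every marker. Mitotic recombination events (crossovers with or
without gene-conversion tracts, interstitial conversions, break-induced
replication, deletions, aneuploidy) are planted with the correct segregation
semantics for the two daughter-cell sectors (D1, D2) of a sectored colony,
and two-channel hybridization-ratio tables are emitted with multiplicative
lognormal noise.

Event classes
-------------
CO_SIMPLE
    Reciprocal crossover without detectable conversion: both sectors show a
    transition at the same point, homozygous for opposite haplotypes distally.
CO_3TO1
    Crossover with a 3:1 conversion tract: the donor-haplotype homozygosity
    extends over the tract in one sector only (single-chromatid break, SCB).
CO_4TO0
    Crossover with a 4:0 tract: both sectors homozygous for the donor over
    the tract (double sister-chromatid break, DSCB).
CO_HYBRID
    3:1/4:0 hybrid tract: the half adjacent to the exchange is shared by both
    sectors, the proximal half is one-sector only (DSCB).
BIR_TERMINAL
    Non-reciprocal terminal LOH in one sector only.
NCO_INTERSTITIAL
    Interstitial conversion tract in one sector only.
DELETION
    Loss of one homolog over the tract in one sector (hemizygous).
ANEUPLOIDY
    Whole-chromosome copy-number change in one sector (monosomy by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel, MarkerMap

EVENT_CLASSES = (
    "CO_SIMPLE",
    "CO_3TO1",
    "CO_4TO0",
    "CO_HYBRID",
    "NCO_INTERSTITIAL",
    "BIR_TERMINAL",
    "DELETION",
    "ANEUPLOIDY",
)
CROSSOVER_CLASSES = ("CO_SIMPLE", "CO_3TO1", "CO_4TO0", "CO_HYBRID")
SECTORS = ("D1", "D2")

#: Default class mix for rate-based simulation: proportions of LOH event
#: categories observed in sectored colonies of the NER-deficient strain
#: (47 interstitial, 18 crossovers, 16 BIR, 4 deletions across 12 sectors),
#: with crossovers split 15% no-conversion and, among conversion-bearing
#: crossovers, 76% 3:1 (SCB) vs 24% DSCB (equally 4:0 and hybrid).
DEFAULT_CLASS_MIX: dict[str, float] = {
    "NCO_INTERSTITIAL": 0.553,
    "CO_SIMPLE": 0.032,
    "CO_3TO1": 0.137,
    "CO_4TO0": 0.022,
    "CO_HYBRID": 0.021,
    "BIR_TERMINAL": 0.188,
    "DELETION": 0.047,
}


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth recombination event.

    ``donor`` is the haplotype whose sequence is over-represented by the
    event (for DELETION it is the *retained* haplotype; the other homolog is
    lost). ``side`` orients terminal classes toward the left or right
    telomere. ``sector`` is the daughter cell carrying the one-sector part of
    the pattern.
    """

    event_class: str
    chrom: str
    tract_start: int
    tract_end: int
    donor: str = "W"
    break_type: str = "NA"
    sector: str = "D1"
    side: str = "R"
    copy_number: int = 1  # ANEUPLOIDY only: resulting chromosome copy number

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.donor not in ("W", "Y"):
            raise ValueError("donor must be 'W' or 'Y'")
        if self.sector not in SECTORS:
            raise ValueError("sector must be 'D1' or 'D2'")
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if self.tract_start > self.tract_end:
            raise ValueError("tract_start must be <= tract_end")
        expected = EXPECTED_BREAK_TYPE.get(self.event_class, "NA")
        if self.break_type == "NA" and expected != "NA":
            object.__setattr__(self, "break_type", expected)
        elif self.break_type != expected:
            raise ValueError(
                f"{self.event_class} implies break type {expected}, "
                f"got {self.break_type}"
            )


#: Break-type implied by each class: 3:1 tracts arise from single-chromatid
#: breaks, 4:0 and hybrid tracts from double sister-chromatid breaks;
#: crossovers without conversion are unclassifiable and non-CO classes get NA.
EXPECTED_BREAK_TYPE: dict[str, str] = {
    "CO_3TO1": "SCB",
    "CO_4TO0": "DSCB",
    "CO_HYBRID": "DSCB",
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise on channel means keyed by allele copy
    count: ratio = mean(copies) * exp(Normal(0, sigma)).

    Copy counts above 2 extrapolate linearly from the copy-1 -> copy-2 step.
    A ratio of ~1 indicates heterozygosity (one copy of each allele).
    """

    mean_copy0: float = 0.2
    mean_copy1: float = 1.0
    mean_copy2: float = 1.8
    sigma: float = 0.15

    def __post_init__(self):
        if not (self.mean_copy2 > self.mean_copy1 > self.mean_copy0 >= 0):
            raise ValueError("channel means must satisfy copy2 > copy1 > copy0 >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def mean(self, copies: np.ndarray) -> np.ndarray:
        copies = np.asarray(copies)
        base = np.array([self.mean_copy0, self.mean_copy1, self.mean_copy2])
        out = base[np.clip(copies, 0, 2)]
        extra = np.maximum(copies - 2, 0)
        return out + extra * (self.mean_copy2 - self.mean_copy1)


class SectorTruth:
    """Per-marker allele copy counts and genotype states for both sectors.

    With zero planted events every marker carries one W and one Y copy (HET)
    and every chromosome is disomic in both sectors.
    """

    def __init__(self, markers: MarkerMap):
        n = len(markers)
        self.markers = markers
        self.w_copies = {s: np.ones(n, dtype=np.int8) for s in SECTORS}
        self.y_copies = {s: np.ones(n, dtype=np.int8) for s in SECTORS}
        self.chrom_copy = {
            s: {c: 2 for c in markers.genome.names} for s in SECTORS
        }

    def states(self, sector: str) -> np.ndarray:
        """Genotype state per marker: HET, HOM_W, HOM_Y, DEL_W, DEL_Y."""
        w = self.w_copies[sector]
        y = self.y_copies[sector]
        out = np.full(len(self.markers), "HET", dtype="<U8")
        out[(w >= 1) & (y == 0)] = "HOM_W"
        out[(w == 0) & (y >= 1)] = "HOM_Y"
        out[(w == 0) & (y == 1)] = "DEL_W"
        out[(w == 1) & (y == 0)] = "DEL_Y"
        out[(w >= 2) & (y == 0)] = "HOM_W"
        out[(w == 0) & (y >= 2)] = "HOM_Y"
        return out


def build_marker_map(
    genome: GenomeModel, n_markers: int, seed: int
) -> MarkerMap:
    """Draw a marker map with markers allocated to chromosomes proportionally
    to length (multinomial) and positions uniform without replacement.

    Every chromosome receives at least one marker.
    """
    n_chroms = len(genome)
    if n_markers < n_chroms:
        raise ValueError("need at least one marker per chromosome")
    if n_markers > genome.total_length:
        raise ValueError(
            f"cannot place {n_markers} unique markers in a "
            f"{genome.total_length} bp genome"
        )
    rng = np.random.default_rng(seed)
    lengths = np.array(list(genome.lengths.values()), dtype=float)
    counts = rng.multinomial(n_markers, lengths / lengths.sum())
    # Enforce per-chromosome bounds: >= 1 and <= chromosome length.
    counts = np.minimum(counts, lengths.astype(int))
    while counts.min() < 1 or counts.sum() != n_markers:
        short = counts.sum() < n_markers
        if counts.min() < 1:
            i = int(np.argmin(counts))
            j = int(np.argmax(counts - (counts <= 1) * 10**9))
            counts[i] += 1
            counts[j] -= 1
        elif short:
            room = lengths.astype(int) - counts
            counts[int(np.argmax(room))] += 1
        else:
            j = int(np.argmax(counts))
            counts[j] -= 1
    rows = []
    for (chrom, length), c in zip(genome.lengths.items(), counts):
        pos = np.sort(rng.choice(length, size=int(c), replace=False) + 1)
        for k, p in enumerate(pos):
            rows.append((chrom, int(p), f"{chrom}_{k:05d}"))
    return MarkerMap(pd.DataFrame(rows, columns=["chrom", "pos", "id"]), genome)


def _affected_span(ev: PlantedEvent, chrom_len: int) -> tuple[int, int]:
    """Full interval of markers whose state the event may change."""
    if ev.event_class == "ANEUPLOIDY":
        return (1, chrom_len)
    if ev.event_class in CROSSOVER_CLASSES + ("BIR_TERMINAL",):
        if ev.side == "R":
            return (ev.tract_start, chrom_len)
        return (1, ev.tract_end)
    return (ev.tract_start, ev.tract_end)


def plant_events(
    markers: MarkerMap,
    events: list[PlantedEvent],
    seed: int | None = None,
) -> tuple[SectorTruth, list[PlantedEvent]]:
    """Realize planted events as sector genotype states.

    Events on one chromosome must not overlap in their affected spans. A
    tract containing zero markers raises a warning but the event is retained
    in the returned truth list. ``seed`` is accepted for interface symmetry;
    planting itself is deterministic.
    """
    truth = SectorTruth(markers)
    by_chrom: dict[str, list[PlantedEvent]] = {}
    for ev in events:
        if ev.chrom not in markers.genome.lengths:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        chrom_len = markers.genome.lengths[ev.chrom]
        if ev.tract_end > chrom_len or ev.tract_start < 1:
            raise ValueError(f"tract outside {ev.chrom} bounds")
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        chrom_len = markers.genome.lengths[chrom]
        spans = sorted(_affected_span(e, chrom_len) for e in evs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping event tracts on {chrom}")
    for ev in events:
        _apply_event(truth, ev)
    return truth, list(events)


def _set(truth, sector, mask, w, y):
    truth.w_copies[sector][mask] = w
    truth.y_copies[sector][mask] = y


def _apply_event(truth: SectorTruth, ev: PlantedEvent) -> None:
    markers = truth.markers
    sl = markers.chrom_slice(ev.chrom)
    pos = markers.positions
    on_chrom = np.zeros(len(markers), dtype=bool)
    on_chrom[sl] = True
    in_tract = on_chrom & (pos >= ev.tract_start) & (pos <= ev.tract_end)
    if ev.event_class != "ANEUPLOIDY" and not in_tract.any():
        if ev.event_class not in ("CO_SIMPLE",):
            warnings.warn(
                f"{ev.event_class} tract on {ev.chrom} "
                f"[{ev.tract_start}-{ev.tract_end}] contains no markers",
                stacklevel=3,
            )
    d1 = ev.sector
    d2 = "D2" if d1 == "D1" else "D1"
    dw, dy = (2, 0) if ev.donor == "W" else (0, 2)   # homozygous donor
    ow, oy = (0, 2) if ev.donor == "W" else (2, 0)   # homozygous other
    if ev.side == "R":
        distal = on_chrom & (pos > ev.tract_end)
        distal_simple = on_chrom & (pos > ev.tract_start)
    else:
        distal = on_chrom & (pos < ev.tract_start)
        distal_simple = on_chrom & (pos < ev.tract_end)

    cls = ev.event_class
    if cls == "CO_SIMPLE":
        _set(truth, d1, distal_simple, dw, dy)
        _set(truth, d2, distal_simple, ow, oy)
    elif cls == "CO_3TO1":
        _set(truth, d1, in_tract | distal, dw, dy)
        _set(truth, d2, distal, ow, oy)
    elif cls == "CO_4TO0":
        _set(truth, d1, in_tract | distal, dw, dy)
        _set(truth, d2, in_tract, dw, dy)
        _set(truth, d2, distal, ow, oy)
    elif cls == "CO_HYBRID":
        # The tract half adjacent to the exchange point is shared (4:0-like),
        # the proximal half is one-sector (3:1-like).
        mid = (ev.tract_start + ev.tract_end) // 2
        if ev.side == "R":
            shared = in_tract & (pos > mid)
        else:
            shared = in_tract & (pos <= mid)
        _set(truth, d1, in_tract | distal, dw, dy)
        _set(truth, d2, shared, dw, dy)
        _set(truth, d2, distal, ow, oy)
    elif cls == "BIR_TERMINAL":
        _set(truth, d1, in_tract | distal, dw, dy)
    elif cls == "NCO_INTERSTITIAL":
        _set(truth, d1, in_tract, dw, dy)
    elif cls == "DELETION":
        # donor = retained haplotype; the other homolog's segment is lost
        rw, ry = (1, 0) if ev.donor == "W" else (0, 1)
        _set(truth, d1, in_tract, rw, ry)
    elif cls == "ANEUPLOIDY":
        if ev.copy_number == 1:
            rw, ry = (1, 0) if ev.donor == "W" else (0, 1)
            _set(truth, d1, on_chrom, rw, ry)
        else:
            gw, gy = (2, 1) if ev.donor == "W" else (1, 2)
            _set(truth, d1, on_chrom, gw, gy)
        truth.chrom_copy[d1][ev.chrom] = ev.copy_number


def simulate_ratios(
    truth: SectorTruth,
    markers: MarkerMap,
    noise: NoiseModel,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Emit one two-channel ratio table per sector.

    Each marker's W- and Y-channel ratios are the channel means for its
    underlying allele copy counts times independent lognormal noise.
    """
    if truth.markers is not markers and len(truth.markers) != len(markers):
        raise ValueError("truth and markers are not aligned")
    rng = np.random.default_rng(seed)
    out = {}
    for sector in SECTORS:
        w_mean = noise.mean(truth.w_copies[sector])
        y_mean = noise.mean(truth.y_copies[sector])
        n = len(markers)
        if noise.sigma == 0:
            w = w_mean.astype(float)
            y = y_mean.astype(float)
        else:
            w = w_mean * np.exp(rng.normal(0.0, noise.sigma, n))
            y = y_mean * np.exp(rng.normal(0.0, noise.sigma, n))
        df = markers.df.copy()
        df["ratio_W"] = w
        df["ratio_Y"] = y
        out[sector] = df
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for rate-based colony simulation.

    Defaults emulate sectored colonies of the NER-deficient strain at 1 J/m^2:
    a Poisson number of events per colony (mean 7.1) with the observed class
    mix, conversion-tract lengths lognormal with medians 4.3 kb (NCO) and
    8.7 kb (CO-associated), and lognormal spread 0.8 on the log scale.
    """

    mean_events: float = 7.1
    class_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    nco_median_kb: float = 4.3
    co_median_kb: float = 8.7
    tract_log_sigma: float = 0.8
    deletion_median_kb: float = 10.0
    aneuploidy_prob: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    #: minimum markers a planted tract (or tract compartment) must span so
    #: the event is detectable at the segmentation sensitivity limit
    min_tract_markers: int = 3
    #: bp kept clear of the telomere / arm boundary for terminal events
    margin_bp: int = 30_000


def _draw_tract_len(rng, median_kb: float, log_sigma: float) -> int:
    return max(200, int(round(np.exp(rng.normal(np.log(median_kb * 1000), log_sigma)))))


def _markers_in(markers: MarkerMap, chrom: str, lo: int, hi: int) -> int:
    pos = markers.chrom_positions(chrom)
    return int(np.searchsorted(pos, hi, "right") - np.searchsorted(pos, lo, "left"))


def plan_colony_events(
    markers: MarkerMap, config: SimulationConfig, rng: np.random.Generator
) -> list[PlantedEvent]:
    """Draw the planted events for one colony in rate mode.

    At most one event per chromosome arm (arms split at the chromosome
    midpoint), so planted events never produce ambiguous multi-event
    patterns; placement is resampled until every tract compartment spans at
    least ``min_tract_markers`` markers.
    """
    genome = markers.genome
    arms = [(c, s) for c in genome.names for s in ("L", "R")]
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], float)
    probs /= probs.sum()
    n_events = min(rng.poisson(config.mean_events), len(arms))
    chosen = rng.choice(len(arms), size=n_events, replace=False)
    events: list[PlantedEvent] = []
    for k in chosen:
        chrom, side = arms[int(k)]
        cls = classes[int(rng.choice(len(classes), p=probs))]
        ev = _place_event(markers, chrom, side, cls, config, rng)
        if ev is not None:
            events.append(ev)
    if rng.random() < config.aneuploidy_prob:
        used = {e.chrom for e in events}
        free = [c for c in genome.names if c not in used]
        if free:
            chrom = free[int(rng.choice(len(free)))]
            events.append(
                PlantedEvent(
                    "ANEUPLOIDY", chrom, 1, genome.lengths[chrom],
                    donor="W" if rng.random() < 0.5 else "Y",
                    sector="D1" if rng.random() < 0.5 else "D2",
                )
            )
    return events


def _place_event(
    markers: MarkerMap,
    chrom: str,
    side: str,
    cls: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> PlantedEvent | None:
    chrom_len = markers.genome.lengths[chrom]
    mid = chrom_len // 2
    arm_lo, arm_hi = (1, mid) if side == "L" else (mid + 1, chrom_len)
    donor = "W" if rng.random() < 0.5 else "Y"
    sector = "D1" if rng.random() < 0.5 else "D2"
    m = config.min_tract_markers
    margin = config.margin_bp
    for _ in range(max_tries):
        if cls == "CO_SIMPLE":
            lo = arm_lo + margin if side == "L" else arm_lo
            hi = arm_hi if side == "L" else arm_hi - margin
            if hi <= lo:
                break
            c = int(rng.integers(lo, hi))
            distal = (arm_lo, c) if side == "L" else (c, chrom_len)
            # distal region must be callable in both sectors
            if side == "L":
                distal = (1, c - 1)
            else:
                distal = (c + 1, chrom_len)
            if _markers_in(markers, chrom, *distal) >= m:
                return PlantedEvent(cls, chrom, c, c, donor, sector=sector, side=side)
        elif cls in ("CO_3TO1", "CO_4TO0", "CO_HYBRID", "NCO_INTERSTITIAL", "DELETION"):
            median = {
                "NCO_INTERSTITIAL": config.nco_median_kb,
                "DELETION": config.deletion_median_kb,
            }.get(cls, config.co_median_kb)
            L = _draw_tract_len(rng, median, config.tract_log_sigma)
            if cls in CROSSOVER_CLASSES:
                # tract sits proximal to the exchange; distal LOH runs to the
                # telomere on `side`
                if side == "R":
                    hi_end = chrom_len - margin
                    lo_start = arm_lo
                else:
                    hi_end = arm_hi
                    lo_start = 1 + margin
                if hi_end - L <= lo_start:
                    continue
                start = int(rng.integers(lo_start, hi_end - L))
                end = start + L
                distal = (end + 1, chrom_len) if side == "R" else (1, start - 1)
                if cls == "CO_HYBRID":
                    # each half of the tract (shared and one-sector parts)
                    # must be independently detectable
                    half = (start + end) // 2
                    tract_ok = (
                        _markers_in(markers, chrom, start, half) >= m
                        and _markers_in(markers, chrom, half + 1, end) >= m
                    )
                else:
                    tract_ok = _markers_in(markers, chrom, start, end) >= m
                if tract_ok and _markers_in(markers, chrom, *distal) >= m:
                    return PlantedEvent(
                        cls, chrom, start, end, donor, sector=sector, side=side
                    )
            else:
                lo = arm_lo + max(margin, 1000)
                hi = arm_hi - max(margin, 1000) - L
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                end = start + L
                if _markers_in(markers, chrom, start, end) >= m:
                    return PlantedEvent(
                        cls, chrom, start, end, donor, sector=sector, side=side
                    )
        elif cls == "BIR_TERMINAL":
            L = _draw_tract_len(rng, 80.0, config.tract_log_sigma)  # long terminal
            if side == "R":
                start = max(arm_lo, chrom_len - L)
                start = min(start, chrom_len - margin)
                start, end = max(1, start), chrom_len
            else:
                end = min(arm_hi, L)
                end = max(end, margin)
                start, end = 1, min(end, chrom_len)
            if _markers_in(markers, chrom, start, end) >= m:
                return PlantedEvent(
                    cls, chrom, start, end, donor, sector=sector, side=side
                )
        else:
            break
    return None


def plan_class_coverage_events(
    markers: MarkerMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    classes: tuple[str, ...] = EVENT_CLASSES,
) -> list[PlantedEvent]:
    """Plant one event of every requested class on distinct chromosomes of
    one colony, with randomized arms, donors, sectors, and tract placement.
    Used to exercise every pattern in round-trip validation."""
    genome = markers.genome
    chroms = list(genome.names)
    rng.shuffle(chroms)
    events: list[PlantedEvent] = []
    ci = 0
    for cls in classes:
        while ci < len(chroms):
            chrom = chroms[ci]
            ci += 1
            if cls == "ANEUPLOIDY":
                events.append(
                    PlantedEvent(
                        "ANEUPLOIDY", chrom, 1, genome.lengths[chrom],
                        donor="W" if rng.random() < 0.5 else "Y",
                        sector="D1" if rng.random() < 0.5 else "D2",
                    )
                )
                break
            side = "L" if rng.random() < 0.5 else "R"
            ev = _place_event(markers, chrom, side, cls, config, rng)
            if ev is not None:
                events.append(ev)
                break
    return events


@dataclass
class SimulatedColony:
    colony_id: str
    events: list[PlantedEvent]
    truth: SectorTruth
    ratios: dict[str, pd.DataFrame]


def simulate_colonies(
    markers: MarkerMap,
    n_colonies: int,
    config: SimulationConfig,
    seed: int,
    explicit_events: list[list[PlantedEvent]] | None = None,
) -> list[SimulatedColony]:
    """Simulate sectored colonies end to end.

    ``explicit_events`` overrides rate-mode planning (one event list per
    colony) so tests can cover every class deterministically. Identical seeds
    give bit-identical output.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_colonies)
    colonies = []
    for i in range(n_colonies):
        rng = np.random.default_rng(children[i])
        if explicit_events is not None:
            events = explicit_events[i]
        else:
            events = plan_colony_events(markers, config, rng)
        truth, events = plant_events(markers, events)
        ratio_seed = int(rng.integers(0, 2**31 - 1))
        ratios = simulate_ratios(truth, markers, config.noise, ratio_seed)
        colonies.append(SimulatedColony(f"colony{i:04d}", events, truth, ratios))
    return colonies


def events_to_frame(events: list[PlantedEvent], colony_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "colony": colony_id,
            "class": e.event_class,
            "chrom": e.chrom,
            "tract_start": e.tract_start,
            "tract_end": e.tract_end,
            "donor": e.donor,
            "break_type": e.break_type,
            "sector": e.sector,
            "side": e.side,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "colony", "class", "chrom", "tract_start", "tract_end",
            "donor", "break_type", "sector", "side",
        ],
    )
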