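"""End-to-end orchestration: ratios -> genotypes -> segments -> events.

Also provides the ground-truth recovery evaluation used to validate the
pipeline on simulated colonies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    LOHEvent,
    classify_colony,
    detect_aneuploidy,
    raw_mad,
    split_distant_events,
    summarize_colony,
)
from .genome import MarkerMap
from .genotyping import (
    CallingThresholds,
    Segment,
    call_marker_states,
    segment_genome,
    smooth_calls,
)
from .simulate import PlantedEvent, SimulatedColony
from .stats import tract_length

CONVERSION_CLASSES = ("CO_3TO1", "CO_4TO0", "CO_HYBRID", "NCO_INTERSTITIAL")


@dataclass(frozen=True)
class AnalysisParams:
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    smoothing_flank: int = 3
    min_markers: int = 3
    mad_scale: str = "raw"  # 'raw' or 'normal' (R-style 1.4826 factor)
    #: fixed (median_kb, mad_kb) for the distant-event split rule; None
    #: computes them from the current dataset's conversion tracts
    split_rule: tuple[float, float] | None = None
    apply_split_rule: bool = True
    detect_ploidy: bool = True


def genotype_sample(
    ratios: pd.DataFrame, markers: MarkerMap, params: AnalysisParams
) -> list[Segment]:
    """Call, smooth, and segment one sample's ratio table."""
    calls = call_marker_states(ratios, params.thresholds)
    calls = smooth_calls(calls, params.smoothing_flank)
    return segment_genome(calls, markers, params.min_markers)


def analyze_colony(
    ratios: dict[str, pd.DataFrame],
    markers: MarkerMap,
    colony: str = "",
    mode: str = "SECTORED_PAIR",
    params: AnalysisParams | None = None,
) -> list[LOHEvent]:
    """Genotype and classify one colony (without the dataset-level split
    rule, which needs the full dataset's tract distribution)."""
    params = params or AnalysisParams()
    segments = {
        sector: genotype_sample(df, markers, params) for sector, df in ratios.items()
    }
    events = classify_colony(
        segments, markers, colony=colony, mode=mode, min_markers=params.min_markers
    )
    if params.detect_ploidy:
        events = _merge_ploidy_calls(events, ratios, markers, colony)
    return events


def _merge_ploidy_calls(events, ratios, markers, colony):
    """Add trisomy calls from the chromosome-mean ratio route (monosomy is
    already visible as a chromosome-wide hemizygous pattern)."""
    called = {(e.chrom, e.sector) for e in events if e.event_class == "ANEUPLOIDY"}
    extra = []
    for sector, df in ratios.items():
        for chrom, copy in detect_aneuploidy(df, markers).items():
            if copy > 2 and (chrom, sector) not in called:
                pos = markers.chrom_positions(chrom)
                extra.append(
                    LOHEvent(
                        colony, "ANEUPLOIDY", chrom,
                        int(pos[0]), int(pos[-1]),
                        sector=sector, flags=(f"copy_{copy}",),
                    )
                )
    # drop pattern events on trisomic chromosomes: their marker states are
    # not interpretable as LOH
    tris = {(e.chrom, e.sector) for e in extra}
    events = [e for e in events if (e.chrom, e.sector) not in tris]
    return events + extra


def conversion_tract_lengths(
    events: list[LOHEvent], markers: MarkerMap
) -> np.ndarray:
    """Lengths (kb) of all conversion tracts among classified events."""
    return np.array(
        [
            tract_length(e, markers)
            for e in events
            if e.event_class in CONVERSION_CLASSES
        ]
    )


def analyze_colonies(
    colonies: list[tuple[str, dict[str, pd.DataFrame]]],
    markers: MarkerMap,
    mode: str = "SECTORED_PAIR",
    params: AnalysisParams | None = None,
) -> tuple[list[LOHEvent], list]:
    """Analyze a batch of colonies and apply the distant-event split rule
    with the dataset's own conversion-tract median/MAD (unless fixed values
    were supplied). Returns (events, colony summaries)."""
    params = params or AnalysisParams()
    all_events: list[LOHEvent] = []
    per_colony: dict[str, list[LOHEvent]] = {}
    for colony, ratios in colonies:
        evs = analyze_colony(ratios, markers, colony=colony, mode=mode, params=params)
        per_colony[colony] = evs
        all_events.extend(evs)
    if params.apply_split_rule:
        if params.split_rule is not None:
            med, mad = params.split_rule
        else:
            lengths = conversion_tract_lengths(all_events, markers)
            if lengths.size >= 2:
                med = float(np.median(lengths))
                mad = raw_mad(lengths, scale=params.mad_scale)
            else:
                med, mad = 0.0, 0.0
        all_events = split_distant_events(all_events, med, mad)
        per_colony = {}
        for ev in all_events:
            per_colony.setdefault(ev.colony, []).append(ev)
    summaries = [
        summarize_colony(evs, colony=c) for c, evs in per_colony.items()
    ]
    return all_events, summaries


# ---------------------------------------------------------------------------
# ground-truth evaluation


@dataclass
class RecoveryReport:
    n_planted: int
    n_class_correct: int
    n_boundary_ok: int
    n_false_positive: int
    matches: list[tuple[PlantedEvent, LOHEvent | None]]

    @property
    def class_accuracy(self) -> float:
        return self.n_class_correct / self.n_planted if self.n_planted else 1.0

    @property
    def boundary_accuracy(self) -> float:
        return self.n_boundary_ok / self.n_planted if self.n_planted else 1.0


def _boundary_tol(markers: MarkerMap, chrom: str, b: int) -> int:
    """One inter-marker gap: width of the marker interval containing ``b``
    (chromosome ends count as flanking points)."""
    pos = markers.chrom_positions(chrom)
    chrom_len = markers.genome.lengths[chrom]
    j = int(np.searchsorted(pos, b))
    left = int(pos[j - 1]) if j > 0 else 1
    right = int(pos[j]) if j < len(pos) else chrom_len
    return max(right - left, 1)


def evaluate_recovery(
    simulated: list[SimulatedColony],
    recovered: dict[str, list[LOHEvent]],
    markers: MarkerMap,
) -> RecoveryReport:
    """Match planted events against recovered events per colony/chromosome.

    A planted event is class-correct when a recovered event on the same
    chromosome overlaps its affected span and carries the same class;
    boundary-ok additionally requires both tract boundaries (the transition
    midpoint, for simple crossovers) within one inter-marker gap of truth.
    """
    n_planted = n_correct = n_boundary = 0
    n_recovered_total = 0
    matched_ids: set[int] = set()
    matches = []
    for col in simulated:
        evs = recovered.get(col.colony_id, [])
        n_recovered_total += len(evs)
        for planted in col.events:
            n_planted += 1
            cands = [e for e in evs if e.chrom == planted.chrom]
            best = None
            for e in cands:
                lo = max(e.tract_start, planted.tract_start)
                hi = min(e.tract_end, planted.tract_end)
                near = (
                    hi >= lo
                    or planted.event_class == "CO_SIMPLE"
                    and abs(e.tract_start - planted.tract_start) <= 50_000
                )
                if near and (best is None or e.event_class == planted.event_class):
                    best = e
            matches.append((planted, best))
            if best is None:
                continue
            matched_ids.add(id(best))
            if best.event_class != planted.event_class:
                continue
            n_correct += 1
            if planted.event_class == "CO_SIMPLE":
                tol = _boundary_tol(markers, planted.chrom, planted.tract_start)
                ok = abs(best.tract_start - planted.tract_start) <= tol
            elif planted.event_class == "ANEUPLOIDY":
                ok = True
            else:
                tol_s = _boundary_tol(markers, planted.chrom, planted.tract_start)
                tol_e = _boundary_tol(markers, planted.chrom, planted.tract_end)
                ok = (
                    abs(best.tract_start - planted.tract_start) <= tol_s
                    and abs(best.tract_end - planted.tract_end) <= tol_e
                )
            n_boundary += ok
    n_fp = n_recovered_total - len(matched_ids)
    return RecoveryReport(n_planted, n_correct, n_boundary, n_fp, matches)
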