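"""Per-marker genotype calling and run-length segmentation.

Converts two-channel hybridization ratios (experimental vs heterozygous
control; a value of ~1 on both channels indicates heterozygosity) into
genotype states, removes isolated miscalls, and segments each chromosome
into maximal runs of one state with transition intervals between runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MarkerMap

log = logging.getLogger(__name__)

STATES = ("HET", "HOM_W", "HOM_Y", "DEL_W", "DEL_Y", "UNCALLED")
HOM_STATES = ("HOM_W", "HOM_Y")
DEL_STATES = ("DEL_W", "DEL_Y")


@dataclass(frozen=True)
class CallingThresholds:
    """Ratio bands for genotype calling.

    HET requires both channels in [het_lo, het_hi]; HOM_X requires channel X
    >= hom_hi with the other channel <= hom_lo; DEL_X requires channel X <=
    hom_lo with the other channel in the heterozygous band (one homolog lost,
    the remaining channel at single-copy level). Anything else is UNCALLED.
    """

    het_lo: float = 0.7
    het_hi: float = 1.3
    hom_hi: float = 1.4
    hom_lo: float = 0.5

    def __post_init__(self):
        if not self.het_hi < self.hom_hi:
            raise ValueError("het_hi must be < hom_hi")
        if not self.hom_lo < self.het_lo:
            raise ValueError("hom_lo must be < het_lo")


def call_marker_states(
    ratios: pd.DataFrame, thresholds: CallingThresholds | None = None
) -> np.ndarray:
    """Call each marker's genotype state from its W/Y channel ratios."""
    t = thresholds or CallingThresholds()
    w = ratios["ratio_W"].to_numpy(float)
    y = ratios["ratio_Y"].to_numpy(float)
    if not (np.isfinite(w).all() and np.isfinite(y).all()):
        raise ValueError("ratios must be finite")
    if (w < 0).any() or (y < 0).any():
        raise ValueError("ratios must be non-negative")
    w_het = (w >= t.het_lo) & (w <= t.het_hi)
    y_het = (y >= t.het_lo) & (y <= t.het_hi)
    out = np.full(len(w), "UNCALLED", dtype="<U8")
    out[w_het & y_het] = "HET"
    out[(w >= t.hom_hi) & (y <= t.hom_lo)] = "HOM_W"
    out[(y >= t.hom_hi) & (w <= t.hom_lo)] = "HOM_Y"
    out[(w <= t.hom_lo) & y_het] = "DEL_W"
    out[(y <= t.hom_lo) & w_het] = "DEL_Y"
    return out


def smooth_calls(calls: np.ndarray, flank: int = 3) -> np.ndarray:
    """Remove isolated single-marker miscalls.

    A single marker disagreeing with >= ``flank`` identically-called markers
    on both sides is reassigned to the flanking call; UNCALLED markers
    inherit the flanking call when both sides agree. One left-to-right pass.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    calls = np.asarray(calls)
    out = calls.copy()
    n = len(out)
    if n < 2 * flank + 1:
        return out
    # length of the uniform run in the original calls starting at each index
    change = np.flatnonzero(calls[1:] != calls[:-1]) + 1
    bounds = np.concatenate([[0], change, [n]])
    rlen = np.concatenate(
        [np.arange(b - a, 0, -1) for a, b in zip(bounds[:-1], bounds[1:])]
    )
    run = 1  # uniform run length ending at i-1 in the smoothed output
    for i in range(1, n - flank):
        if i >= flank and run >= flank and rlen[i + 1] >= flank:
            state = out[i - 1]
            if state == calls[i + 1] and state != "UNCALLED" and out[i] != state:
                out[i] = state
        run = run + 1 if out[i] == out[i - 1] else 1
    return out


@dataclass(frozen=True)
class Segment:
    """Maximal run of one genotype state on a chromosome.

    ``start``/``end`` are the 1-based positions of the first and last called
    marker in the run; ``first``/``last`` their indices in the marker map.
    """

    chrom: str
    first: int
    last: int
    start: int
    end: int
    state: str
    n_markers: int


@dataclass(frozen=True)
class Transition:
    """Boundary between two adjacent segments.

    The true breakpoint lies in the uncertainty interval between the last
    marker of the left segment and the first marker of the right segment;
    ``midpoint`` is the floor of their mean.
    """

    chrom: str
    left_state: str
    right_state: str
    interval_start: int
    interval_end: int

    @property
    def midpoint(self) -> int:
        return (self.interval_start + self.interval_end) // 2


def segment_genome(
    calls: np.ndarray,
    markers: MarkerMap,
    min_markers: int = 3,
) -> list[Segment]:
    """Segment all chromosomes into maximal same-state runs.

    UNCALLED markers are skipped (never segment-breaking). Non-HET runs with
    fewer than ``min_markers`` markers are absorbed into the surrounding HET
    state and logged — conversion tracts covering fewer markers than this are
    therefore invisible (documented sensitivity limit).
    """
    if min_markers < 1:
        raise ValueError("min_markers must be >= 1")
    calls = np.asarray(calls)
    segments: list[Segment] = []
    for chrom in markers.genome.names:
        sl = markers.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        idx = np.arange(sl.start, sl.stop)
        states = calls[sl]
        called = states != "UNCALLED"
        idx, states = idx[called], states[called]
        if idx.size == 0:
            continue
        merged = _absorb_short_runs(states, min_markers, chrom)
        pos = markers.positions
        for s, e, lab in merged:
            segments.append(
                Segment(
                    chrom=chrom,
                    first=int(idx[s]),
                    last=int(idx[e - 1]),
                    start=int(pos[idx[s]]),
                    end=int(pos[idx[e - 1]]),
                    state=lab,
                    n_markers=e - s,
                )
            )
    return segments


def _absorb_short_runs(
    states: np.ndarray, min_markers: int, chrom: str
) -> list[tuple[int, int, str]]:
    """RLE the state sequence and iteratively absorb non-HET runs shorter
    than ``min_markers`` into the surrounding state.

    A short run flanked by two runs of the same state joins that state; at a
    chromosome end it joins its only neighbour; between differing states it
    joins HET if either neighbour is HET, else the longer neighbour. HET
    runs are never absorbed.
    """
    runs = [(s, e, str(states[s])) for s, e in _run_lengths(states)]
    changed = True
    while changed:
        changed = False
        for k, (s, e, lab) in enumerate(runs):
            if lab == "HET" or (e - s) >= min_markers:
                continue
            left = runs[k - 1][2] if k > 0 else None
            right = runs[k + 1][2] if k < len(runs) - 1 else None
            if left is None and right is None:
                continue
            if left is None:
                new = right
            elif right is None:
                new = left
            elif left == right:
                new = left
            elif left == "HET" or right == "HET":
                new = "HET"
            else:
                llen = runs[k - 1][1] - runs[k - 1][0]
                rlen = runs[k + 1][1] - runs[k + 1][0]
                new = left if llen >= rlen else right
            log.info(
                "absorbing %d-marker %s run on %s into %s", e - s, lab, chrom, new
            )
            runs[k] = (s, e, new)
            # merge adjacent equal-state runs
            merged: list[tuple[int, int, str]] = []
            for run in runs:
                if merged and merged[-1][2] == run[2]:
                    merged[-1] = (merged[-1][0], run[1], run[2])
                else:
                    merged.append(run)
            runs = merged
            changed = True
            break
    return runs


def _run_lengths(states: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal equal-value runs."""
    if len(states) == 0:
        return []
    change = np.flatnonzero(states[1:] != states[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def find_transitions(segments: list[Segment]) -> list[Transition]:
    """One transition per adjacent segment pair, per chromosome, in order."""
    out: list[Transition] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.first)
        for a, b in zip(segs, segs[1:]):
            out.append(
                Transition(chrom, a.state, b.state, a.end, b.start)
            )
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "state": s.state,
                "n_markers": s.n_markers,
            }
            for s in segments
        ],
        columns=["chrom", "start", "end", "state", "n_markers"],
    )
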