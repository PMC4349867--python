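"""Classification of LOH events from paired-sector (or single-colony) segments.

A sectored colony arises when the two reciprocal products of a mitotic
crossover segregate into the two daughter cells; comparing the genotype
segmentation of the two sectors (D1, D2) distinguishes:

* reciprocal crossovers (terminal homozygosity for opposite haplotypes in the
  two sectors), with or without an adjacent gene-conversion tract;
* 3:1 conversion tracts (donor homozygosity extends the tract in one sector
  only; diagnostic of a single-chromatid break, SCB);
* 4:0 and 3:1/4:0 hybrid tracts (tract shared by both sectors, wholly or in
  the half adjacent to the exchange; diagnostic of a double sister-chromatid
  break, DSCB);
* break-induced replication (non-reciprocal terminal LOH in one sector);
* interstitial conversions unassociated with crossovers (one sector only);
* hemizygous deletions and whole-chromosome aneuploidy.

In single-colony mode terminal LOH cannot be split into crossover vs BIR and
is pooled into a CO_BIR category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import MarkerMap
from .genotyping import DEL_STATES, HOM_STATES, Segment

log = logging.getLogger(__name__)

CATEGORY_BY_CLASS = {
    "NCO_INTERSTITIAL": "INTERSTITIAL",
    "CO_SIMPLE": "CROSSOVER",
    "CO_3TO1": "CROSSOVER",
    "CO_4TO0": "CROSSOVER",
    "CO_HYBRID": "CROSSOVER",
    "BIR_TERMINAL": "BIR",
    "DELETION": "OTHER",
    "ANEUPLOIDY": "OTHER",
}

BREAK_TYPE_BY_CLASS = {
    "CO_3TO1": "SCB",
    "CO_4TO0": "DSCB",
    "CO_HYBRID": "DSCB",
    "CO_SIMPLE": "UNCLASSIFIED",
}


@dataclass(frozen=True)
class LOHEvent:
    """A classified LOH event.

    ``tract_start``/``tract_end`` are the positions of the first and last
    affected marker (for CO_SIMPLE, the transition midpoint). ``flank_left``
    and ``flank_right`` are the nearest heterozygous marker positions outside
    the tract (None at a chromosome end, with a ``chrom_end`` flag).
    """

    colony: str
    event_class: str
    chrom: str
    tract_start: int
    tract_end: int
    donor: str = ""
    sector: str = ""
    break_type: str = "NA"
    category: str = ""
    flank_left: int | None = None
    flank_right: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.category:
            object.__setattr__(
                self, "category", CATEGORY_BY_CLASS.get(self.event_class, "OTHER")
            )


def assign_break_type(event: LOHEvent) -> LOHEvent:
    """SCB for 3:1 tracts, DSCB for 4:0/hybrid, UNCLASSIFIED for crossovers
    without detectable conversion, NA otherwise."""
    bt = BREAK_TYPE_BY_CLASS.get(event.event_class, "NA")
    return replace(event, break_type=bt)


@dataclass
class ColonySummary:
    """Event tallies for one colony (deletions and ploidy changes are tallied
    separately from the LOH total)."""

    colony: str
    interstitial: int = 0
    crossovers: int = 0
    bir: int = 0
    co_bir: int = 0
    deletions: int = 0
    ploidy_changes: int = 0

    @property
    def total_loh(self) -> int:
        return self.interstitial + self.crossovers + self.bir + self.co_bir


def summarize_colony(
    events: list[LOHEvent],
    colony: str = "",
    exclude_chrom: str | None = None,
) -> ColonySummary:
    """Tally events by category; ``exclude_chrom`` drops events on the
    selected chromosome so that only unselected events are counted."""
    s = ColonySummary(colony=colony)
    for ev in events:
        if exclude_chrom is not None and ev.chrom == exclude_chrom:
            continue
        if ev.category == "INTERSTITIAL":
            s.interstitial += 1
        elif ev.category == "CROSSOVER":
            s.crossovers += 1
        elif ev.category == "BIR":
            s.bir += 1
        elif ev.category == "CO_BIR":
            s.co_bir += 1
        elif ev.event_class == "DELETION":
            s.deletions += 1
        elif ev.event_class == "ANEUPLOIDY":
            s.ploidy_changes += 1
    return s


# ---------------------------------------------------------------------------
# sector matching


def _fill_states(segments: list[Segment], markers: MarkerMap) -> np.ndarray:
    """Per-marker state array implied by a segmentation; markers outside all
    segments (uncalled at chromosome ends) inherit the nearest segment."""
    out = np.full(len(markers), "", dtype="<U8")
    for seg in segments:
        out[seg.first : seg.last + 1] = seg.state
    for chrom in markers.genome.names:
        sl = markers.chrom_slice(chrom)
        states = out[sl]
        if len(states) == 0:
            continue
        known = np.flatnonzero(states != "")
        if known.size == 0:
            continue
        states[: known[0]] = states[known[0]]
        states[known[-1] + 1 :] = states[known[-1]]
        # interior gaps cannot occur: segments cover all called markers and
        # uncalled interior markers lie between segment bounds
        empty = np.flatnonzero(states == "")
        for i in empty:
            states[i] = states[i - 1]
        out[sl] = states
    return out


def match_sectors(
    d1: list[Segment],
    d2: list[Segment],
    markers: MarkerMap,
) -> dict[str, list[tuple[str, str, int, int]]]:
    """Align two sector segmentations into joint state blocks.

    Returns, per chromosome, an ordered list of ``(state_d1, state_d2,
    first_marker_index, last_marker_index)`` blocks over maximal marker runs
    where neither sector changes state (breakpoint union of the two
    segmentations).
    """
    s1 = _fill_states(d1, markers)
    s2 = _fill_states(d2, markers)
    out: dict[str, list[tuple[str, str, int, int]]] = {}
    for chrom in markers.genome.names:
        sl = markers.chrom_slice(chrom)
        if sl.stop == sl.start:
            continue
        a, b = s1[sl], s2[sl]
        if (a == "").all() or (b == "").all():
            log.info("chromosome %s has no called markers in a sector", chrom)
            continue
        pair_change = np.flatnonzero((a[1:] != a[:-1]) | (b[1:] != b[:-1])) + 1
        bounds = np.concatenate([[0], pair_change, [len(a)]])
        blocks = [
            (str(a[i]), str(b[i]), sl.start + int(i), sl.start + int(j) - 1)
            for i, j in zip(bounds[:-1], bounds[1:])
        ]
        out[chrom] = blocks
    return out


# ---------------------------------------------------------------------------
# chromosome classification


def _hom_hap(state: str) -> str | None:
    return state[-1] if state in HOM_STATES else None


def _flanks(
    markers: MarkerMap, chrom: str, first: int, last: int
) -> tuple[int | None, int | None, tuple[str, ...]]:
    """Nearest marker positions flanking the marker index range [first, last]
    on ``chrom``; None (plus a flag) at a chromosome end."""
    sl = markers.chrom_slice(chrom)
    pos = markers.positions
    flags: tuple[str, ...] = ()
    left = int(pos[first - 1]) if first > sl.start else None
    right = int(pos[last + 1]) if last < sl.stop - 1 else None
    if left is None or right is None:
        flags = ("chrom_end",)
    return left, right, flags


def classify_chromosome(
    blocks: list[tuple[str, str, int, int]],
    markers: MarkerMap,
    chrom: str,
    colony: str = "",
    mode: str = "SECTORED_PAIR",
    min_markers: int = 3,
) -> list[LOHEvent]:
    """Classify the joint LOH pattern of one chromosome into events.

    Rules are applied in order: chromosome-wide copy anomaly (monosomy seen
    as a chromosome-wide hemizygous pattern) -> ANEUPLOIDY; hemizygous
    blocks -> DELETION; terminal homozygosity for opposite haplotypes in
    both sectors -> crossover subtyped by the conversion region between the
    two sector transitions (empty: simple; one-sector: 3:1; shared: 4:0;
    mixed: hybrid); terminal homozygosity in exactly one sector ->
    BIR_TERMINAL (flagged: a second-division crossover cannot be excluded);
    interstitial one-sector homozygosity -> NCO_INTERSTITIAL.
    """
    events: list[LOHEvent] = []
    if not blocks:
        return events
    pos = markers.positions
    n_total = sum(last - first + 1 for _, _, first, last in blocks)

    # (1) chromosome-wide hemizygosity in one sector => monosomy
    for si in (0, 1):
        covered = sum(
            last - first + 1
            for s1, s2, first, last in blocks
            if (s1 if si == 0 else s2) in DEL_STATES
        )
        if covered >= 0.95 * n_total and n_total >= 3:
            state = next(
                (s1 if si == 0 else s2)
                for s1, s2, *_ in blocks
                if (s1 if si == 0 else s2) in DEL_STATES
            )
            donor = "Y" if state == "DEL_W" else "W"  # retained haplotype
            first = blocks[0][2]
            last = blocks[-1][3]
            events.append(
                LOHEvent(
                    colony, "ANEUPLOIDY", chrom,
                    int(pos[first]), int(pos[last]),
                    donor=donor, sector=f"D{si + 1}",
                    flags=("monosomy",),
                )
            )
            return events

    consumed = np.zeros(len(blocks), dtype=bool)

    # (2) hemizygous blocks => deletions
    for bi, (s1, s2, first, last) in enumerate(blocks):
        for si, state in ((0, s1), (1, s2)):
            if state in DEL_STATES:
                fl, fr, flags = _flanks(markers, chrom, first, last)
                events.append(
                    LOHEvent(
                        colony, "DELETION", chrom,
                        int(pos[first]), int(pos[last]),
                        donor="Y" if state == "DEL_W" else "W",
                        sector=f"D{si + 1}",
                        flank_left=fl, flank_right=fr, flags=flags,
                    )
                )
                consumed[bi] = True

    if mode == "SINGLE_COLONY":
        events.extend(
            _classify_single(blocks, consumed, markers, chrom, colony)
        )
        return [assign_break_type(e) if e.break_type == "NA" else e for e in events]

    # (3)/(4) terminal structure at each chromosome end
    for end in ("L", "R"):
        ev, used = _classify_terminal(
            blocks, consumed, markers, chrom, colony, end, min_markers
        )
        events.extend(ev)
        consumed |= used

    # (5) interstitial one-sector homozygosity => NCO
    for bi, (s1, s2, first, last) in enumerate(blocks):
        if consumed[bi]:
            continue
        h1, h2 = _hom_hap(s1), _hom_hap(s2)
        if h1 and s2 == "HET":
            si, donor = 0, h1
        elif h2 and s1 == "HET":
            si, donor = 1, h2
        elif h1 and h2 and h1 == h2:
            si, donor = 0, h1  # shared interstitial tract (DSCB conversion)
        else:
            continue
        fl, fr, flags = _flanks(markers, chrom, first, last)
        if h1 and h2:
            flags = flags + ("shared_tract",)
        events.append(
            LOHEvent(
                colony, "NCO_INTERSTITIAL", chrom,
                int(pos[first]), int(pos[last]),
                donor=donor, sector=f"D{si + 1}",
                flank_left=fl, flank_right=fr, flags=flags,
            )
        )
        consumed[bi] = True

    return [assign_break_type(e) for e in events]


def _classify_terminal(blocks, consumed, markers, chrom, colony, end, min_markers=3):
    """Crossover / BIR logic at one chromosome end.

    Conversion sub-tracts (the one-sector and shared parts) must each span
    at least ``min_markers`` markers to be trusted: below that, boundary
    markers lost to noise would masquerade as conversion structure, so the
    event is demoted (hybrid -> 4:0 or 3:1, any conversion -> simple
    crossover when the whole region is below the limit).
    """
    pos = markers.positions
    events: list[LOHEvent] = []
    used = np.zeros(len(blocks), dtype=bool)
    order = range(len(blocks) - 1, -1, -1) if end == "R" else range(len(blocks))
    order = [i for i in order if not consumed[i]]
    if not order:
        return events, used
    edge = order[0]
    s1, s2, *_ = blocks[edge]
    h1, h2 = _hom_hap(s1), _hom_hap(s2)

    if h1 and h2 and h1 != h2:
        # reciprocal terminal homozygosity: crossover at this end
        distal = [edge]
        for i in order[1:]:
            if blocks[i][0] == s1 and blocks[i][1] == s2:
                distal.append(i)
            else:
                break
        conv: list[int] = []
        donor = None
        for i in order[len(distal):]:
            b1, b2 = blocks[i][0], blocks[i][1]
            g1, g2 = _hom_hap(b1), _hom_hap(b2)
            cand = g1 or g2
            if cand is None or (b1 != "HET" and g1 is None) or (
                b2 != "HET" and g2 is None
            ):
                break
            if g1 and g2 and g1 != g2:
                break
            if donor is None:
                donor = cand
            if (g1 and g1 != donor) or (g2 and g2 != donor):
                break
            conv.append(i)
        used[distal + conv] = True
        exchange_first = blocks[min(distal, key=lambda i: blocks[i][2])][2]
        exchange_last = blocks[max(distal, key=lambda i: blocks[i][3])][3]
        shared = [i for i in conv if _hom_hap(blocks[i][0]) and _hom_hap(blocks[i][1])]
        single = [i for i in conv if i not in shared]
        n_shared = sum(blocks[i][3] - blocks[i][2] + 1 for i in shared)
        n_single = sum(blocks[i][3] - blocks[i][2] + 1 for i in single)
        if n_shared + n_single < min_markers:
            # no trustworthy conversion: simple crossover whose transition
            # uncertainty interval spans any sub-threshold conversion blocks
            if end == "R":
                first = min(
                    [exchange_first] + [blocks[i][2] for i in conv]
                )
                fl, _, flags = _flanks(markers, chrom, first, first)
                lo = fl if fl is not None else int(pos[first])
                hi = int(pos[exchange_first])
            else:
                last = max([exchange_last] + [blocks[i][3] for i in conv])
                _, fr2, flags = _flanks(markers, chrom, last, last)
                lo = int(pos[exchange_last])
                hi = fr2 if fr2 is not None else int(pos[last])
            mid = (lo + hi) // 2
            events.append(
                LOHEvent(
                    colony, "CO_SIMPLE", chrom, mid, mid,
                    donor="", flank_left=lo, flank_right=hi, flags=flags,
                )
            )
            return events, used
        if n_shared < min_markers:
            cls = "CO_3TO1"
        elif n_single < min_markers:
            cls = "CO_4TO0"
        else:
            cls = "CO_HYBRID"
        conv_first = min(blocks[i][2] for i in conv)
        conv_last = max(blocks[i][3] for i in conv)
        # sector carrying the one-sector part of the tract
        sector = ""
        if single:
            b1 = blocks[single[0]][0]
            sector = "D1" if _hom_hap(b1) else "D2"
        fl, fr, flags = _flanks(markers, chrom, conv_first, conv_last)
        if end == "R":
            fr = int(pos[exchange_first])  # distal flank is the exchange side
            flags = ()
        else:
            fl = int(pos[exchange_last])
            flags = ()
        events.append(
            LOHEvent(
                colony, cls, chrom,
                int(pos[conv_first]), int(pos[conv_last]),
                donor=donor or "", sector=sector,
                flank_left=fl, flank_right=fr, flags=flags,
            )
        )
        return events, used

    for si, h in ((0, h1), (1, h2)):
        other = blocks[edge][1 - si]
        if h and other == "HET":
            run = [edge]
            for i in order[1:]:
                b = blocks[i]
                if _hom_hap(b[si]) == h and b[1 - si] == "HET":
                    run.append(i)
                else:
                    break
            used[run] = True
            first = min(blocks[i][2] for i in run)
            last = max(blocks[i][3] for i in run)
            fl, fr, flags = _flanks(markers, chrom, first, last)
            events.append(
                LOHEvent(
                    colony, "BIR_TERMINAL", chrom,
                    int(pos[first]), int(pos[last]),
                    donor=h, sector=f"D{si + 1}",
                    flank_left=fl, flank_right=fr,
                    flags=flags + ("possible_second_division_crossover",),
                )
            )
            return events, used
    return events, used


def _classify_single(blocks, consumed, markers, chrom, colony):
    """Single-colony mode: terminal LOH pools crossovers and BIR."""
    pos = markers.positions
    events: list[LOHEvent] = []
    open_blocks = [i for i in range(len(blocks)) if not consumed[i]]
    runs: list[list[int]] = []
    for i in open_blocks:
        h = _hom_hap(blocks[i][0])
        if h is None:
            continue
        if runs and runs[-1][-1] == i - 1 and _hom_hap(blocks[runs[-1][-1]][0]) == h:
            runs[-1].append(i)
        else:
            runs.append([i])
    last_idx = len(blocks) - 1
    for run in runs:
        first = blocks[run[0]][2]
        last = blocks[run[-1]][3]
        donor = _hom_hap(blocks[run[0]][0])
        terminal = run[0] == 0 or run[-1] == last_idx
        fl, fr, flags = _flanks(markers, chrom, first, last)
        if terminal:
            events.append(
                LOHEvent(
                    colony, "BIR_TERMINAL", chrom,
                    int(pos[first]), int(pos[last]),
                    donor=donor, sector="D1", category="CO_BIR",
                    flank_left=fl, flank_right=fr,
                    flags=flags + ("co_bir_indistinguishable",),
                )
            )
        else:
            events.append(
                LOHEvent(
                    colony, "NCO_INTERSTITIAL", chrom,
                    int(pos[first]), int(pos[last]),
                    donor=donor, sector="D1",
                    flank_left=fl, flank_right=fr, flags=flags,
                )
            )
    return events


def classify_colony(
    segments: dict[str, list[Segment]],
    markers: MarkerMap,
    colony: str = "",
    mode: str = "SECTORED_PAIR",
    min_markers: int = 3,
) -> list[LOHEvent]:
    """Classify all chromosomes of one colony.

    ``segments`` maps sector name to its segment list ("D1" and "D2" for
    SECTORED_PAIR; "D1" only for SINGLE_COLONY).
    """
    if mode == "SECTORED_PAIR":
        aligned = match_sectors(segments["D1"], segments["D2"], markers)
    elif mode == "SINGLE_COLONY":
        s1 = _fill_states(segments["D1"], markers)
        aligned = {}
        for chrom in markers.genome.names:
            sl = markers.chrom_slice(chrom)
            if sl.stop == sl.start:
                continue
            a = s1[sl]
            if (a == "").all():
                continue
            change = np.flatnonzero(a[1:] != a[:-1]) + 1
            bounds = np.concatenate([[0], change, [len(a)]])
            aligned[chrom] = [
                (str(a[i]), str(a[i]), sl.start + int(i), sl.start + int(j) - 1)
                for i, j in zip(bounds[:-1], bounds[1:])
            ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    events: list[LOHEvent] = []
    for chrom, blocks in aligned.items():
        events.extend(
            classify_chromosome(
                blocks, markers, chrom,
                colony=colony, mode=mode, min_markers=min_markers,
            )
        )
    return events


# ---------------------------------------------------------------------------
# distant-event splitting


def raw_mad(values, scale: str = "raw") -> float:
    """Median absolute deviation; ``scale='normal'`` applies the 1.4826
    consistency factor (the R default)."""
    values = np.asarray(values, float)
    med = np.median(values)
    mad = float(np.median(np.abs(values - med)))
    if scale == "normal":
        mad *= 1.4826
    elif scale != "raw":
        raise ValueError("scale must be 'raw' or 'normal'")
    return mad


_MERGE_PRIORITY = {
    "CO_HYBRID": 5, "CO_4TO0": 4, "CO_3TO1": 3, "CO_SIMPLE": 2,
    "BIR_TERMINAL": 1, "NCO_INTERSTITIAL": 0,
}


def split_distant_events(
    events: list[LOHEvent],
    tract_median_kb: float,
    tract_mad_kb: float,
) -> list[LOHEvent]:
    """Apply the distance rule for multi-block chromosomes: LOH blocks on one
    chromosome separated by a heterozygous gap larger than
    median + 2 * MAD (kb) stay distinct events; smaller gaps merge the blocks
    into one event whose tract spans both.
    """
    if tract_median_kb < 0 or tract_mad_kb < 0:
        raise ValueError("median and MAD must be >= 0")
    threshold_bp = (tract_median_kb + 2 * tract_mad_kb) * 1000.0
    out: list[LOHEvent] = []
    keyed: dict[tuple, list[LOHEvent]] = {}
    for ev in events:
        if ev.event_class in ("DELETION", "ANEUPLOIDY"):
            out.append(ev)
            continue
        keyed.setdefault((ev.colony, ev.chrom, ev.sector), []).append(ev)
    for group in keyed.values():
        group = sorted(group, key=lambda e: e.tract_start)
        current = group[0]
        for nxt in group[1:]:
            gap = nxt.tract_start - current.tract_end
            if gap <= threshold_bp:
                lead = max(
                    (current, nxt),
                    key=lambda e: _MERGE_PRIORITY.get(e.event_class, -1),
                )
                current = replace(
                    lead,
                    tract_start=current.tract_start,
                    tract_end=nxt.tract_end,
                    flank_left=current.flank_left,
                    flank_right=nxt.flank_right,
                    flags=tuple(sorted(set(current.flags + nxt.flags + ("merged",)))),
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def events_to_frame(events: list[LOHEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "colony": e.colony,
                "chrom": e.chrom,
                "class": e.event_class,
                "category": e.category,
                "break_type": e.break_type,
                "tract_start": e.tract_start,
                "tract_end": e.tract_end,
                "donor": e.donor,
                "sector": e.sector,
                "flank_left": e.flank_left,
                "flank_right": e.flank_right,
                "flags": ";".join(e.flags),
            }
            for e in events
        ],
        columns=[
            "colony", "chrom", "class", "category", "break_type",
            "tract_start", "tract_end", "donor", "sector",
            "flank_left", "flank_right", "flags",
        ],
    )


def detect_aneuploidy(
    ratios: pd.DataFrame,
    markers: MarkerMap,
    z_threshold: float = 8.0,
) -> dict[str, int]:
    """Chromosome-wide copy calls from total (W+Y) ratio means.

    At disomy the expected total ratio per marker is ~2 (one copy of each
    allele, or two of one and none of the other); monosomy gives ~1.2 and
    trisomy ~2.8 under the default channel means. A chromosome is called
    aneuploid when its mean total is nearer the monosomic/trisomic
    expectation than the disomic one and the z statistic against disomy
    exceeds ``z_threshold``. Returns chromosome -> called copy number.
    """
    total = ratios["ratio_W"].to_numpy(float) + ratios["ratio_Y"].to_numpy(float)
    out: dict[str, int] = {}
    for chrom in markers.genome.names:
        sl = markers.chrom_slice(chrom)
        t = total[sl]
        if len(t) < 10:
            continue
        m = float(np.mean(t))
        se = float(np.std(t, ddof=1) / np.sqrt(len(t)))
        se = max(se, 1e-9)
        expectations = {1: 1.2, 2: 2.0, 3: 2.8}
        nearest = min(expectations, key=lambda k: abs(m - expectations[k]))
        if nearest != 2 and abs(m - 2.0) / se > z_threshold:
            out[chrom] = nearest
    return out
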