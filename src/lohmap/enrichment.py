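"""Genomic-element enrichment at LOH breakpoint regions.

The DNA lesions that initiate recombination lie near the transitions between
heterozygous and homozygous regions: for conversion-bearing events, between
the heterozygous markers flanking the conversion tract; for crossovers
without conversion, within the transition uncertainty interval. This module
tests whether classes of genomic elements (replication origins, tRNA genes,
G4 motifs, ...) are over- or under-represented in those regions relative to
random placement within the array-covered genome, with step-up FDR
correction across element classes.

Intervals are 1-based inclusive internally; BED input/output is 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .classify import LOHEvent
from .genome import GenomeModel, MarkerMap
from .stats import TestResult, chi_square_gof

log = logging.getLogger(__name__)

Interval = tuple[str, int, int]  # chrom, start, end (1-based inclusive)


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or adjacent intervals per chromosome."""
    out: list[Interval] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if s > e:
            raise ValueError("interval start > end")
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s + 1 for _, s, e in intervals)


def intersect(intervals: list[Interval], mask: list[Interval]) -> list[Interval]:
    """Clip ``intervals`` to the union of ``mask`` (both merged internally)."""
    mask = merge_intervals(mask)
    mask_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in mask:
        mask_by_chrom.setdefault(chrom, []).append((s, e))
    out: list[Interval] = []
    for chrom, s, e in intervals:
        for ms, me in mask_by_chrom.get(chrom, []):
            lo, hi = max(s, ms), min(e, me)
            if lo <= hi:
                out.append((chrom, lo, hi))
    return out


@dataclass(frozen=True)
class CoverageMask:
    """Analyzable (array-covered) genome regions, disjoint and sorted."""

    intervals: list[Interval]

    def __post_init__(self):
        object.__setattr__(self, "intervals", merge_intervals(self.intervals))

    @property
    def length(self) -> int:
        return total_length(self.intervals)

    @classmethod
    def telomere_trimmed(
        cls, genome: GenomeModel, trim_bp: int = 10_000
    ) -> "CoverageMask":
        """Whole genome minus ``trim_bp`` at each chromosome end: regions
        within ~10 kb of the telomeres are repeated and not interrogated by
        the arrays."""
        ivs = [
            (c, 1 + trim_bp, length - trim_bp)
            for c, length in genome.lengths.items()
            if length > 2 * trim_bp
        ]
        return cls(ivs)


@dataclass(frozen=True)
class ElementAnnotation:
    """One class of genomic elements; intervals merged before counting."""

    name: str
    intervals: list[Interval]

    def merged(self) -> list[Interval]:
        return merge_intervals(self.intervals)


@dataclass(frozen=True)
class EnrichmentResult:
    element_class: str
    observed: int
    expected: float
    n_elements: int
    statistic: float
    pvalue: float
    adjusted_pvalue: float
    direction: str  # over / under / none
    tested: bool = True


def derive_breakpoint_regions(
    events: list[LOHEvent],
    markers: MarkerMap,
    mask: CoverageMask,
    include_crossover_transitions: bool = True,
) -> list[Interval]:
    """Breakpoint regions for enrichment testing, clipped to the mask.

    Conversion-bearing events contribute the interval between the flanking
    heterozygous markers; crossovers without conversion contribute the
    transition uncertainty interval (when enabled). Events falling entirely
    outside the mask are dropped with a log entry.
    """
    raw: list[Interval] = []
    for ev in events:
        chrom_len = markers.genome.lengths[ev.chrom]
        if ev.event_class == "CO_SIMPLE":
            if not include_crossover_transitions:
                continue
            lo = ev.flank_left if ev.flank_left is not None else ev.tract_start
            hi = ev.flank_right if ev.flank_right is not None else ev.tract_end
        elif ev.event_class in ("DELETION", "ANEUPLOIDY"):
            continue
        else:
            lo = ev.flank_left if ev.flank_left is not None else 1
            hi = ev.flank_right if ev.flank_right is not None else chrom_len
        clipped = intersect([(ev.chrom, lo, hi)], mask.intervals)
        if not clipped:
            log.info("event region on %s [%d-%d] outside mask", ev.chrom, lo, hi)
            continue
        raw.extend(clipped)
    return merge_intervals(raw) if raw else []


def count_overlaps(regions: list[Interval], annotation: ElementAnnotation) -> int:
    """Number of element instances overlapping any region by >= 1 bp; each
    element (after per-class merging) counted at most once."""
    if not regions:
        return 0
    regions = merge_intervals(regions)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {c for c, _, _ in regions}:
        rs = [(s, e) for c, s, e in regions if c == chrom]
        starts[chrom] = np.array([s for s, _ in rs])
        ends[chrom] = np.array([e for _, e in rs])
    count = 0
    for chrom, s, e in annotation.merged():
        if chrom not in starts:
            continue
        # overlaps region i iff region_start <= e and region_end >= s
        i = np.searchsorted(starts[chrom], e, "right")
        if i > 0 and ends[chrom][i - 1] >= s:
            count += 1
    return count


def expected_count(
    annotation: ElementAnnotation,
    regions: list[Interval],
    mask: CoverageMask,
) -> tuple[float, int]:
    """Expected overlap count under uniform random placement: the number of
    in-mask elements times the fraction of the mask covered by regions.
    Returns (expected, n_elements_in_mask)."""
    if mask.length <= 0:
        raise ValueError("empty coverage mask")
    in_mask = sum(
        1
        for iv in annotation.merged()
        if intersect([iv], mask.intervals)
    )
    region_len = total_length(merge_intervals(regions)) if regions else 0
    return in_mask * region_len / mask.length, in_mask


def permutation_expected_count(
    annotation: ElementAnnotation,
    regions: list[Interval],
    mask: CoverageMask,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation cross-check of the analytic expectation: shuffle the
    regions uniformly within the mask (preserving each region's length) and
    return the mean overlap count over shuffles."""
    if mask.length <= 0:
        raise ValueError("empty coverage mask")
    rng = np.random.default_rng(seed)
    regions = merge_intervals(regions) if regions else []
    if not regions:
        return 0.0
    mask_ivs = mask.intervals
    lens = np.array([e - s + 1 for _, s, e in mask_ivs])
    weights = lens / lens.sum()
    totals = 0
    for _ in range(n_shuffles):
        shuffled: list[Interval] = []
        for _, s, e in regions:
            size = e - s + 1
            for _ in range(50):
                k = int(rng.choice(len(mask_ivs), p=weights))
                mc, ms, me = mask_ivs[k]
                if me - ms + 1 >= size:
                    a = int(rng.integers(ms, me - size + 2))
                    shuffled.append((mc, a, a + size - 1))
                    break
        totals += count_overlaps(shuffled, annotation)
    return totals / n_shuffles


def multiple_test_correction(pvals, q: float = 0.05) -> np.ndarray:
    """Step-up false-discovery-rate adjustment: sort p ascending,
    adjusted_i = min over j >= i of (p_j * m / j), capped at 1."""
    p = np.asarray(pvals, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p
    _, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adj


def enrichment_table(
    annotations: list[ElementAnnotation],
    regions: list[Interval],
    mask: CoverageMask,
    q: float = 0.05,
) -> list[EnrichmentResult]:
    """Per element class: chi-square goodness of fit of (inside, outside)
    element counts against the length-proportional expectation, two-sided,
    with step-up FDR adjustment across classes. Classes whose expected
    inside-count is below 1 (or with no in-mask elements) are reported
    untested."""
    if not annotations:
        raise ValueError("need at least one element class")
    prelim = []
    for ann in annotations:
        exp, m = expected_count(ann, regions, mask)
        obs = count_overlaps(regions, ann)
        testable = m > 0 and exp >= 1 and (m - exp) >= 1
        if testable:
            t = chi_square_gof([obs, m - obs], [exp, m - exp])
        else:
            t = TestResult("chi_square_gof", np.nan, np.nan)
        prelim.append((ann.name, obs, exp, m, t, testable))
    tested_p = [t.pvalue for _, _, _, _, t, ok in prelim if ok]
    adj_iter = iter(multiple_test_correction(tested_p, q=q))
    results = []
    for name, obs, exp, m, t, ok in prelim:
        adj = float(next(adj_iter)) if ok else np.nan
        if ok and adj <= q:
            direction = "over" if obs > exp else "under"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                name, obs, exp, m, t.statistic, t.pvalue, adj, direction, ok
            )
        )
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "element_class": r.element_class,
                "observed": r.observed,
                "expected": r.expected,
                "n_elements": r.n_elements,
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "adjusted_pvalue": r.adjusted_pvalue,
                "direction": r.direction,
                "tested": r.tested,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# BED interface (0-based half-open on disk, 1-based inclusive in memory)


def read_bed(path) -> list[tuple[str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start + 1, end, name))
    return rows


def read_annotations_bed(path) -> list[ElementAnnotation]:
    """Load element classes from a BED file with the class name in column 4
    (a single unnamed class if column 4 is absent)."""
    rows = read_bed(path)
    classes: dict[str, list[Interval]] = {}
    for chrom, s, e, name in rows:
        classes.setdefault(name or "elements", []).append((chrom, s, e))
    return [ElementAnnotation(name, ivs) for name, ivs in classes.items()]


def read_mask_bed(path) -> CoverageMask:
    return CoverageMask([(c, s, e) for c, s, e, _ in read_bed(path)])


def write_bed(intervals: list[Interval], path, name: str = "") -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            suffix = f"\t{name}" if name else ""
            fh.write(f"{chrom}\t{s - 1}\t{e}{suffix}\n")
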