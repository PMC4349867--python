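"""Frequency, fold-change, tract-length, and hypothesis-test statistics.

Standard tests are delegated to scipy/statsmodels behind a small stable
surface: exact (Clopper-Pearson) binomial confidence intervals for sectoring
frequencies, two-sided Fisher exact and Mann-Whitney tests, chi-square
goodness of fit, and a percentile-bootstrap confidence interval for tract
medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .classify import LOHEvent
from .genome import MarkerMap


@dataclass(frozen=True)
class ProportionEstimate:
    successes: int
    trials: int
    frequency: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    pvalue: float


def sector_frequency(k: int, n: int) -> ProportionEstimate:
    """Frequency of sectored colonies with an exact (Clopper-Pearson) 95% CI."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return ProportionEstimate(k, n, k / n, float(lo), float(hi))


def crossover_rate(freq: ProportionEstimate | float) -> float:
    """Rate of mitotic crossovers: twice the sectored-colony frequency (only
    half of crossovers segregate the two recombinant chromosomes into
    different daughter cells)."""
    f = freq.frequency if isinstance(freq, ProportionEstimate) else float(freq)
    return 2.0 * f


def fold_change(a: float | ProportionEstimate, b: float | ProportionEstimate) -> float:
    """Ratio a/b of two frequencies or per-colony means."""
    av = a.frequency if isinstance(a, ProportionEstimate) else float(a)
    bv = b.frequency if isinstance(b, ProportionEstimate) else float(b)
    if bv == 0:
        raise ValueError("zero denominator")
    return av / bv


def format_fold(fold: float) -> str:
    """Display convention: folds >= 10 to the nearest integer, < 10 to two
    decimals."""
    if fold >= 10:
        return f"{fold:.0f}"
    return f"{fold:.2f}"


def tract_length(event: LOHEvent, markers: MarkerMap) -> float:
    """Conversion-tract length in kb by the midpoint convention.

    The tract's true endpoints lie in the inter-marker intervals between the
    outermost converted markers and the flanking heterozygous markers; the
    length is the distance between the midpoints of those two uncertainty
    intervals. At a chromosome end (no flanking heterozygous marker) the
    length is computed to the chromosome end.
    """
    start, end = event.tract_start, event.tract_end
    chrom_len = markers.genome.lengths[event.chrom]
    left = event.flank_left if event.flank_left is not None else 1
    right = event.flank_right if event.flank_right is not None else chrom_len
    up_mid = (left + start) / 2.0
    down_mid = (end + right) / 2.0
    return (down_mid - up_mid) / 1000.0


def median_with_ci(
    lengths, n_boot: int = 10_000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Sample median with a percentile-bootstrap 95% CI."""
    x = np.asarray(lengths, float)
    if x.size < 2:
        raise ValueError("need at least two lengths")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boots = np.median(x[idx], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(np.median(x)), (float(lo), float(hi))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the smaller sample has <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult("mann_whitney", float(res.statistic), float(res.pvalue))


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums the hypergeometric probabilities of all tables with
    the same margins whose probability does not exceed that of the observed
    table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    res = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult("fisher_exact", float(res.statistic), float(res.pvalue))


def chi_square_gof(observed, expected) -> TestResult:
    """Chi-square goodness of fit with k-1 degrees of freedom."""
    obs = np.asarray(observed, float)
    exp = np.asarray(expected, float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same length")
    if (exp <= 0).any():
        raise ValueError("expected counts must be > 0")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    p = float(sps.chi2.sf(stat, df=obs.size - 1))
    return TestResult("chi_square_gof", stat, p)
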