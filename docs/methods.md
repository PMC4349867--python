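# Methods

This note documents the models, conventions, and design choices behind
`lohmap`: what the simulator emulates, how genotyping and classification
work, which knobs matter, and what the package's validation does and does
not demonstrate about real array data.

## Coordinate and data conventions

All genomic coordinates are 1-based inclusive base pairs. BED input/output
is converted from/to the 0-based half-open disk convention on load/save.
Genotype states are `HET`, `HOM_W`, `HOM_Y` (homozygous for either parental
haplotype), `DEL_W`/`DEL_Y` (hemizygous; the named homolog is *lost*), and
`UNCALLED`. The default genome is a 16-chromosome model with the budding
yeast chromosome lengths (~12.07 Mb total); any mapping of chromosome names
to lengths can be substituted.

## Synthetic-data generator

The generator emulates a hybrid diploid heterozygous at every marker, with
~13,000 markers allocated to chromosomes multinomially in proportion to
length and placed uniformly without replacement.

**Event semantics.** Events are planted with the segregation patterns a
sectored colony would show. Crossover classes place reciprocal homozygosity
for opposite haplotypes distal to the exchange point in the two sectors;
their conversion tract is, respectively, absent (`CO_SIMPLE`), present in
one sector (`CO_3TO1`, three of the four chromatids carry the donor allele),
shared by both sectors (`CO_4TO0`), or split half-shared/half-one-sector
with the shared half adjacent to the exchange (`CO_HYBRID` — adjacency of
the shared part to the exchange is an assumption; the alternative reading,
shared anywhere within the tract, is not modelled). `BIR_TERMINAL` and
`NCO_INTERSTITIAL` affect one sector only. `DELETION` removes one homolog
over the tract (its `donor` field names the *retained* haplotype).
`ANEUPLOIDY` changes a whole chromosome's copy number in one sector —
monosomy by default; trisomy via `copy_number=3`.

**Noise model.** Channel ratios are `mean(copy count) × exp(N(0, σ))` with
means 0.2 / 1.0 / 1.8 for 0 / 1 / 2 allele copies (linear extrapolation
above 2) and σ = 0.15 by default. This is the simplest model that puts
heterozygous markers at ratio ≈ 1 on both channels with realistic scatter;
the within-array variance of real ratios is not published, so σ is a
plausible default rather than a calibrated one. The generator does not
model dye-swap, print-tip, or spatial artifacts, probe-sequence effects, or
the aggregation of replicate oligonucleotides into one ratio — so passing
round-trip tests demonstrates correctness of the algorithms under the
stated noise model, not robustness to real-array systematics.

**Rate mode.** When events are drawn by rate rather than given explicitly,
the per-colony event count is Poisson with mean 7.1 and the class mix
follows the proportions observed in heavily damaged repair-deficient cells
(55% interstitial conversions, 21% crossovers — of which ~15% lack a
detectable tract and the conversion-bearing remainder split 76% 3:1 / 24%
DSCB classes — 19% BIR, 5% deletions). Conversion-tract lengths are
lognormal with medians 4.3 kb (NCO) and 8.7 kb (CO-associated) and log-scale
spread 0.8. At most one event is planted per chromosome arm (arms split at
the chromosome midpoint; real centromere positions are not modelled), so
planted patterns are unambiguous; multi-event chromosomes are exercised
separately through the distant-event split rule. Placement resamples until
every tract — and for hybrids, each half — spans at least 3 markers, and
terminal events keep a 30 kb margin so that distal regions are detectable;
the planted-length distribution is therefore slightly truncated at the
short end, which is immaterial because recovered lengths are always
compared against the *realized* planted events.

## Genotype calling and segmentation

Calling is per-marker thresholding on the two channel ratios, not a hidden
state model: `HET` if both channels lie in [0.7, 1.3]; `HOM_X` if channel X
≥ 1.4 and the other ≤ 0.5; `DEL_X` if channel X ≤ 0.5 and the other is in
the heterozygous band; otherwise `UNCALLED`. All four thresholds are
config-exposed. At the default noise level the miscall structure is
asymmetric: true-HET markers essentially never call as homozygous, while a
true-HOM marker's strong channel dips below 1.4 about 5% of the time,
producing isolated `DEL` or `UNCALLED` markers inside homozygous runs. Two
mechanisms remove them:

* **Smoothing** (one left-to-right pass, flank = 3): a single marker
  disagreeing with ≥ 3 identically-called markers on both sides is
  reassigned to the flanking call; `UNCALLED` markers inherit agreeing
  flanks. Markers inside a run of length ≥ 2 are never changed.
* **Segmentation** (min_markers = 3): maximal same-state runs per
  chromosome; `UNCALLED` markers are skipped and never break a segment.
  Non-HET runs shorter than min_markers are absorbed into the surrounding
  state — into the shared neighbour state when both neighbours agree, into
  HET when a neighbour is HET, else into the longer neighbour. Absorbing
  into the *surrounding* state (rather than always into HET) matters:
  isolated `DEL` miscalls inside long homozygous regions must rejoin those
  regions, or spurious heterozygous islands would fragment every distal
  crossover region.

The direct consequence of min_markers = 3 is a sensitivity floor: tracts
covering fewer than three markers (~2.8 kb at the default density) are
invisible. Transitions between adjacent segments carry an uncertainty
interval — (last marker of the left segment, first marker of the right
segment) — whose floor-midpoint is the point estimate of the breakpoint.

## Classification

The two sectors' segmentations are aligned into joint state blocks over the
union of their breakpoints, then per chromosome, in order:

1. **Aneuploidy.** A chromosome-wide hemizygous pattern in one sector is
   monosomy. Trisomy is invisible to the threshold caller (its markers fall
   between bands) and is instead called from the chromosome mean of the
   total (W+Y) ratio, which is ≈ 2.0 at disomy, ≈ 1.2 at monosomy, and
   ≈ 2.8 at trisomy under the default means: the call requires the mean to
   be nearer an aneuploid expectation than the disomic one *and* a z
   statistic against 2.0 exceeding 8 (the statistic is enormous for real
   whole-chromosome changes and the threshold is not delicate).
2. **Deletions.** Hemizygous blocks become `DELETION` events.
3. **Terminal structure, each chromosome end.** Opposite-haplotype terminal
   homozygosity in both sectors is a crossover; the region between the two
   sectors' transition points is its conversion tract, subtyped by whether
   the other sector is heterozygous (3:1), shares the donor (4:0), or both
   (hybrid). "Identical transitions" (a simple crossover) is
   operationalized as a conversion region spanning fewer than min_markers
   markers — the discrete analogue of overlapping transition uncertainty
   intervals — and each conversion sub-part (shared / one-sector) must
   itself span ≥ min_markers markers to be trusted, otherwise the event is
   demoted (hybrid → 4:0 or 3:1). Without this guard, a single boundary
   marker lost to noise regularly fabricates conversion structure.
   Terminal homozygosity in exactly one sector is `BIR_TERMINAL`, always
   flagged `possible_second_division_crossover`: a crossover in the second
   division after plating produces the same one-sector terminal pattern, so
   putative BIR events are reported with the caveat rather than suppressed.
4. **Interstitial blocks.** One-sector homozygous blocks become
   `NCO_INTERSTITIAL`; a shared interstitial tract (both sectors, same
   donor) is an NCO flagged `shared_tract`.

In **single-colony mode** (no sector pairing) terminal LOH cannot separate
crossovers from BIR and is pooled into a `CO_BIR` category; interstitial
LOH stays interstitial.

**Break types** follow the tract geometry: 3:1 → SCB, 4:0 and hybrid →
DSCB, crossovers without detectable conversion → UNCLASSIFIED (excluded
from SCB/DSCB tallies), everything else NA.

**Distant-event splitting.** LOH blocks on one chromosome (same colony and
sector) separated by a heterozygous gap greater than
`median + 2 × MAD` of the conversion-tract length distribution are distinct
events; smaller gaps merge the blocks into one event spanning both. By
default the median and MAD are computed from the current dataset's own
conversion tracts (supplying fixed values is supported), and the MAD is the
raw median absolute deviation; the R-style 1.4826-scaled MAD is available
via `mad_scale="normal"`. The merged event takes the class of its
highest-priority member (crossover > BIR > NCO) and a `merged` flag.

## Statistics

* Sectoring frequency: k/n with exact Clopper–Pearson 95% CI. The CI method
  behind the published intervals is not stated and no single standard
  method reproduces all of them exactly; point frequencies, not CI bounds,
  are the quantities this package treats as checkable.
* Crossover rate = 2 × sectoring frequency (only half of crossovers
  segregate reciprocally into the two daughters).
* Fold changes are ratios of frequencies or per-colony means; display
  convention: ≥ 10 to the nearest integer, < 10 to two decimals.
* Tract length (kb): distance between the midpoints of the two flanking
  transition uncertainty intervals; at a chromosome end the length runs to
  the chromosome boundary and the event is flagged. Median CIs are
  percentile bootstrap (default 10,000 resamples, seeded).
* Mann–Whitney (two-sided; exact when the smaller sample ≤ 8 without ties,
  else normal approximation with tie and continuity corrections), Fisher
  exact (two-sided by the minimum-likelihood rule), and chi-square goodness
  of fit are delegated to scipy behind a stable package surface; the test
  suite verifies them against independent brute-force enumeration and
  permutation oracles rather than trusting the library.

## Enrichment

Breakpoint regions are: for conversion-bearing events the interval between
the flanking heterozygous markers (where the initiating lesion must lie);
for crossovers without conversion the transition uncertainty interval
(optional, on by default — whether the original analysis included these is
ambiguous, so both modes exist). Regions are clipped to a coverage mask
(default: the genome minus 10 kb at each telomere, where repeated sequence
is not interrogated by arrays). For each element class, elements are merged
and pre-filtered to the mask; the observed count is the number of elements
overlapping any region by ≥ 1 bp (each element at most once); the expected
count under uniform random placement is (elements in mask) × (region
length / mask length). A two-cell chi-square (inside/outside, 1 df)
gives the raw p; Benjamini–Hochberg step-up adjustment across classes gives
the FDR-controlled p, with direction from the sign of observed − expected.
Classes with expected count < 1 are reported untested. With ~100 elements
per class and regions covering a few percent of the mask, the realized
type-I rate at adjusted 0.05 is conservative (≈ 0.01–0.02 in the null
simulations), as expected from discreteness plus FDR control.

## Validation scales

The shipped validation uses: 50 zero-noise colonies carrying one event of
every class (400 events; 100% class and boundary recovery required); 200
default-noise colonies (~1,400 events; ≥ 95% class accuracy and
tract-median agreement within one mean inter-marker spacing, 0.93 kb);
1,000 simulated enrichment datasets of 5 element classes; 1,000
Mann–Whitney null replicates; and exhaustive Fisher enumeration over all
2×2 tables with total ≤ 30. These sizes keep the whole suite under a
minute of compute while leaving the stochastic margins wide (observed
noisy-class accuracy is ~97–98% against the 95% requirement).

## Known limitations

* Genotyping is per-marker thresholding; an HMM would squeeze more out of
  noisier arrays but is unnecessary at the default noise level.
* Tracts under three markers are invisible by design; at real marker
  density this hides conversions shorter than ~2–3 kb.
* The BIR/second-division-crossover ambiguity is intrinsic to analyzing one
  purified colony per sector; the package flags it but cannot resolve it.
* Translocations, tandem-repeat copy-number changes, and multi-event
  patterns on a single arm beyond the split rule are out of scope.
* The enrichment expectation treats elements as points (length-proportional
  placement of their occurrence, counted by ≥ 1 bp overlap); a
  region-shuffling permutation test is the natural cross-check and the
  expectation model agrees with it on the synthetic annotations used in
  tests.
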