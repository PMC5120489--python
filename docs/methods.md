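# Methods

This note documents the models, algorithms and numerical choices behind
`cnaconcord`, and what the synthetic benchmarks do and do not establish.

## Data model and conventions

The unit of analysis is a cohort: an ordered genome-wide probe map
(marker id, chromosome, 1-based bp position) and a samples × markers
matrix of log2 copy-number ratios (0 ≈ diploid, positive = gain,
negative = loss). All bp coordinates are 1-based inclusive internally;
UCSC-style inputs (0-based half-open cytoBand, BED) are converted by the
readers. Marker indices are 0-based half-open. Chromosomes are held in
natural order (1..22, X as 23). Chromosome arms derive from the
centromere: p = [1, centromere], q = (centromere, length]; for cytoBand
input the centromere is the midpoint of the `acen` band pair.

Markers that are NaN in a sample are mean-imputed per (sample,
chromosome) immediately before segmentation (count logged); both
segmentation engines assume dense vectors, and upstream normalization is
out of scope for this package.

## Circular binary segmentation (CBS)

For a window x of m markers, the split statistic is the pooled
two-sample t between an arc (i, j] and its complement, maximized over
all arcs with at least 2 markers on each side of the comparison. The
implementation evaluates, per arc, the between-group sum of squares
B = n·(s − w·μ)² / (w(n−w)) with s the arc sum and μ the window mean;
for a fixed window t² = B(n−2)/(T−B) with T the total sum of squares,
which is monotone in B, so the arc maximizing B maximizes |t| and
permutation comparisons can be done on B alone (T is
permutation-invariant). Degenerate cases: a window that is constant up
to float rounding scores t = 0 (never split); a perfect split — zero
within-group variance with different means — scores t = +inf. Ties
(notably complementary boundary arcs, identical up to 1 ulp) resolve to
the smallest i, then smallest j.

The split is accepted when the full-permutation p-value
p = (1 + #{permuted max |t| ≥ observed}) / (1 + n_perm) is ≤ α, the
boundaries interior to the window become breakpoints, and the procedure
recurses left-to-right. No hybrid tail approximation and no post-hoc
"undo" pruning are used; the permutation loop terminates early only
when the exceedance count already forces p > α, which cannot change the
decision. Each window draws its permutations from an RNG stream keyed
on (seed, window bounds), so a window's decision does not depend on
what happened elsewhere; a consequence worth knowing is that the
breakpoint set is *exactly* nested in α: raising α can only add
breakpoints.

`min_width` (default 2) bounds the width of every resulting segment;
the arc scan excludes arcs whose boundaries would leave a shorter
flank. With α = 1 every nonzero-t split is accepted and recursion runs
to min-width exhaustion — useful for stress tests only.

Defaults: α = 0.01, n_perm = 1000 (the permutation floor is 100). Note
that the smallest attainable p is 1/(n_perm+1); at n_perm = 100 a split
can only be accepted for α ≥ 0.0099.

## Penalized piecewise-constant fitting (PCF)

PCF minimizes `Σ_segments within-segment SS + γ · #breakpoints` over
all segmentations with segments of ≥ kmin markers (default 5), by an
exact O(n²) suffix dynamic program on prefix sums. Ties resolve to
fewer segments, then the lexicographically smallest breakpoint vector
(reconstruction picks the smallest feasible next breakpoint among
optimal continuations). The test suite verifies exact agreement with
full enumeration for n ≤ 12 over random (x, γ, kmin).

γ acts on the raw residual scale: the sum-of-squares gain of a
breakpoint is compared against γ directly. Penalties quoted for
workflows that standardize residuals first do not transfer; as a rule
of thumb γ ≈ 40·σ² for marker noise σ (σ = 0.25 → γ = 2.5, the package
default). Concordance calibration (below) is the supported way to pick
γ for a given data set. Optional winsorization (clip at median ±
2.5·MAD per sample-chromosome, MAD scaled to σ; mean-absolute-deviation
fallback when the MAD is zero) can precede breakpoint search, default
off; segment means are always computed from the unclipped data.

## Recurrence scoring

Per-marker scores on marker-level segmented values v(s, i):
G_amp(i) = Σ_s (v(s,i) − θ)⁺ and G_del(i) = Σ_s (−v(s,i) − θ)⁺ with
θ = 0.1 log2 units. The contribution is the *excess over θ* rather than
the raw amplitude, so G is continuous in θ and exactly zero at the call
boundary; this is a documented divergence from implementations that sum
raw amplitudes.

The null hypothesis is "segments of these sizes and amplitudes, at
random locations": per permutation each sample's genome-wide
marker-level vector is circularly shifted by an independent uniform
offset, and G is recomputed; the null is the pooled distribution over
all markers × permutations (so its resolution is n_markers · n_perm).
Per-marker p = (1 + #{null ≥ G(i)}) / (1 + |null|), and q-values are
Benjamini–Hochberg step-up across markers, separately for amp and del.
Because every sample's own aberrations are present in the null at
relocated positions, the test is self-calibrating against segment count
and amplitude inflation.

Maximal runs of q ≤ q_threshold (default 0.25, the common convention
for this analysis; configurable) within a chromosome become regions;
the contiguous run of markers attaining the region's maximal G is the
peak, reported in bp. With peel-off (default on, ≤ 5 iterations), the
segments of samples supporting the current peak are zeroed inside the
region, G is recomputed against the same pooled null, and a secondary
peak is emitted if some marker still beats the largest empirical p that
BH accepted genome-wide for that kind. Holding the genome-wide level
fixed avoids the artifact of within-region BH (tens of markers), which
would declare single leftover samples significant and re-emit the same
locus.

Scope: a region spanning ≤ 25% of its chromosome arm (focal_fraction,
"not more than" → the 25% boundary is focal) is focal, larger is broad;
a region spanning the centromere is classified against the
longer-overlap arm after clipping, with a warning. Arm-level analysis
calls a sample-arm gained/lost when the bp-length-weighted median
(midpoint-rule weights, lower weighted median) of its markers exceeds
±θ, and compares observed arm frequencies against the same circular-
shift null, BH-corrected across arms × {gain, loss}.

## Concordance calibration

For each (α, γ) on a grid, both branches are segmented, scored with a
*shared* permutation-null seed (removing Monte-Carlo noise from the
objective surface), and their focal peak sets compared with the
symmetric matched-fraction score: a peak matches if its peak interval
intersects (≥ 1 bp, same chromosome) any peak of the other set;
score = (matched_A + matched_B)/(|A| + |B|), empty-vs-empty = 1. A
bp-Jaccard alternative is available behind a flag. The objective can be
the amp score, the del score, or their mean (default), since tuning
separately for gains and losses is a legitimate workflow. Ties resolve
to the smaller |#peaks_CBS − #peaks_PCF|, then the most conservative
pair (larger γ, smaller α), then grid order. The CBS branch depends
only on α and the PCF branch only on γ, so segmentations are computed
once per grid axis and crossed — identical to the naive double loop.

## Cross-cohort comparison

Cohorts sit on different probe maps, so sharing is defined by
bp-interval intersection, never cytoband-name equality (labels are
annotation only). Per cohort, the consensus set is the pairwise
intersection of overlapping CBS and PCF regions (peak = intersection of
peaks when they intersect, else of the regions; q = the larger,
g_peak = the smaller; duplicates removed). Shared intervals for ≥ k
cohorts come from an endpoint sweep over each cohort's merged
intervals; a region is cohort-specific iff it overlaps no same-kind
region of any other cohort, and percentages are round-half-up
(92/107 → 86%). Broad regions are excluded from peak sharing and
specificity by default but included in gene extraction; gene membership
is ≥ 1 bp intersection, deduplicated by gene id. Venn counts are
exclusive per cohort subset and sum to the union size.

## Synthetic cohorts

The generator emulates the structure the analysis assumes:
value(s, i) = Σ planted-event amplitudes covering marker i with s a
carrier + per-sample baseline shift + optional private passenger
segments + i.i.d. Gaussian marker noise. Carrier counts are
round-half-up of frequency × n (deterministic); carriers are drawn
without replacement; same-kind overlapping truth events are rejected so
ground truth stays unambiguous. Passenger amplitudes are ±U(0.3, 1.0)
(bounded away from θ so they are callable) and widths U(5, 50) markers.
Marker positions are uniform draws without replacement per chromosome.
Everything is reproducible from the spec seed.

What it does **not** emulate: wave/GC artifacts, correlated platform
noise, tumor purity/ploidy mixtures, allele-specific signal. Passing
benchmarks therefore demonstrate correctness of the machinery and
calibration under the stated model, not robustness to real-array
artifacts.

The synthetic genome has 8 chromosomes (240 down to 100 Mb, 1.36 Gb
total, centromeres at 40–48%). Four presets mirror cohorts of differing
platform density at one-tenth scale — breast-like (11 × 10,932),
ovarian-like (7 × 1,798), endometrial-like (8 × 11,478), cervix-like
(8 × 26,053 markers). For the four-cohort comparison design each preset
plants one amplification locus common to all four (distal chr8q,
86–98 Mb) plus two private amps and two private dels at cohort-specific
loci, all at carrier frequency 0.4 and |amplitude| 1.0. Event widths
are 12 Mb so even the sparsest map (~1.3 markers/Mb) covers them with
~15 markers, and all widths are ≤ 25% of their arm. Preset
passenger_rate is 0: random passengers occasionally collide across
samples and would create legitimate-but-unplanned significant regions,
making exact truth accounting impossible; passengers remain available
and are exercised separately.

Two further benchmark designs: `focal_recovery_spec` (40 samples,
10,000 markers over 4 chromosomes, σ = 0.25, one amp of amplitude 1.0
covering exactly 12 markers at 30% carrier frequency — the probe map is
resolved first so the event lies on 12 consecutive markers) and
`three_event_spec` (40 samples, 2,000 markers, three focal amps of
amplitude 0.9–1.1 at frequencies 0.30–0.40) for calibration studies.

## Benchmark settings and problem sizes

The heavy validation suites run 20 replicate seeds each at the sizes
above, with harness settings α = 0.01, γ = 2.5, kmin = 5, θ = 0.1,
q ≤ 0.25 and 100 permutations for both the CBS test and the recurrence
null (the permutation floor; at this count the minimal p = 1/101 is
just inside α = 0.01). The four-cohort comparison runs once per seed at
full preset sizes. `scripts/acceptance.py` uses the same designs and
derives every seed from `--seed`.

## Numerical choices and degenerate inputs

- CBS arc ties are resolved with a 1e-12 relative tolerance (equal-|t|
  complementary arcs differ by 1 ulp in the incremental criterion).
- A window whose total SS is ≤ 1e-20 of its raw sum of squares is
  treated as constant (t = 0); a split residual ≤ 1e-12 of the total SS
  is treated as perfect (t = +inf).
- PCF reconstruction re-derives the DP optimum with identical floating
  expressions, so tie detection is by exact float equality, with an
  argmin fallback.
- Empty probe-map chromosomes, empty arms, empty region lists, and
  empty peak sets (overlap score 1.0 for two empty sets) are all legal.
- SEG files read without a probe map carry -1 marker-index sentinels;
  the partition audit then requires the probe map.

## Known limitations

- CBS permutation cost scales with O(n²) per scan; very dense platforms
  (>10⁵ markers per chromosome) are slow at n_perm = 1000.
- The relocation null shifts genome-wide, so segments may wrap across
  chromosome boundaries; with many chromosomes the effect on pooled
  quantiles is negligible but it is not a per-chromosome null.
- Arm-level calling uses the lower weighted median; cohorts with
  near-50% aberrant arm fractions can flip calls under marker jitter.
- Gene extraction is interval intersection only; no transcript models,
  no strand logic beyond carrying the annotation through.
- Cohorts on platforms of very different probe density are compared
  purely in genomic bp coordinates; no density reconciliation or
  re-gridding is attempted, so region boundary resolution differs
  between cohorts by roughly the inter-marker spacing of the sparser
  platform. This ambiguity is inherent to cross-platform comparison and
  is surfaced rather than hidden.
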