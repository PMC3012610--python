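# Methods

This note documents the models and procedures implemented in `cypwaves`,
the defaults chosen where the design was open, and what the synthetic data
do and do not establish.

## Gene registry and tandem clusters

The registry is a literal transcription of the curated zebrafish CYP
annotation (Zv8 assembly, Ensembl release 58 coordinates): 96 rows, one per
annotated locus, with 1-based inclusive transcript coordinates as printed.
Two loci (CYP2X10, CYP2X12) appear twice with `c1`/`c2` suffixes — exact
duplicate copies attributed to the assembly process — and the counting
convention is therefore *one gene = one distinct base name*, giving 94
genes. Genes supported by EST evidence but absent from the assembly
(CYP46A5, CYP2AA13) carry `missing_from_assembly`, have no coordinates, and
still count as genes. Six genes (CYP2AA6, CYP2AA13, CYP2P8, CYP2X6, CYP2X9,
CYP46A5) are absent from the microarray probe set and lack the `on_array`
flag, leaving 88 array-covered genes. One printed coordinate (CYP8B2's
transcript end) is internally inconsistent with its neighbours and is kept
as printed; it affects no shipped analysis.

Tandem arrays are detected by single-linkage grouping of same-family genes
along a chromosome: sort by transcript start (ties by end, then name) and
split whenever the gap from the running maximum end to the next start
exceeds `max_gap`. The default `max_gap` is 100 kb: all intra-array gaps in
the curated table are below ~25 kb, while the nearest distinct neighbouring
cluster (the CYP2AE pair downstream of the CYP2AA array) is ~230 kb away,
so the default separates every documented array without splitting any.
Coordinate conversions (BED 0-based half-open; GFF3 1-based) are localized
in the export functions.

## Synthetic time-course generator

The generator emulates the developmental expression design: embryos sampled
at 3, 6, 12, 24, 36 and 48 hours post-fertilization, four independently
maintained dishes as biological replicates, and every probe printed twice
per single-color array. Per probe, a log2 baseline ~ Normal(8, 2) receives
an archetype effect:

| archetype | effect (log2) | default parameters |
|---|---|---|
| maternal_decay | linear decline from 3 hpf | slope −0.15 /h |
| unimodal_wave | Gaussian bump | amplitude U(1, 3.5), center 24 hpf, width (σ) 6 h |
| bimodal | bumps at the first and last timepoints | amplitude U(1, 3.5), width 6 h |
| flat | none | — |
| below_background | replaced by linear Normal(4, 1) truncated ≥ 0 | flagged not-above-background |

Noise is multiplicative (normal in log2): replicate σ = 0.25 and spot
σ = 0.10 by default. Each array gets a monotone affine distortion
`y = a + b·x` in log2 (a ~ U(−0.5, 0.5), b ~ U(0.8, 1.25)), emulating
between-scanner/hybridization intensity differences while preserving rank
order. Linear signals are clipped at 65 535 (16-bit scanner) with a
saturation flag. The default archetype mix (15% maternal, 25% wave, 5%
bimodal, 50% flat, 5% below background) reflects a transcriptome in which a
substantial minority of transcripts is strongly temporally regulated; the
wave center is fixed at 24 hpf by default so that a planted archetype is a
coherent co-expression wave rather than a smear of shapes. The planted DE
flag covers the three temporal archetypes (maternal, wave, bimodal):
below-background probes carry no temporal signal and are removed by QC, so
they are not counted as differentially expressed truth.

What the generator does **not** emulate: spatial array artifacts, dye
chemistry and feature-extraction background detrending (flags are taken as
given), probe-sequence effects, and correlated regulation across probes
beyond the shared archetype shapes. Recovery results on these data
therefore demonstrate correctness of the algorithms under the stated error
model, not performance on any real hybridization.

## Signal conditioning

Raw linear signals are floored at 5 units before any transformation. The
baseline array is the one whose per-array median signal is the median of
all per-array medians (even count → lower median; residual ties → first
array). Every other array is normalized to the baseline in log2 space:

1. **Rank-invariant probes** — starting from all probes, each round ranks
   the surviving set on both arrays (average ranks on ties) and keeps
   probes with |rank difference| ≤ `threshold_fraction` × current set size,
   to a fixed point (defaults: 0.02, at most 30 rounds; both exposed as
   configuration since the historical constants are not published). An
   empty selection is an error advising a larger threshold.
2. **Curve fit** — invariant (target, baseline) pairs are sorted by target
   value; control points pair each target value with the centered running
   median of baseline values (window = min(101, ~10% of the set), odd; near
   the ends the window shrinks symmetrically so monotone input maps through
   exactly). A cumulative maximum enforces monotone output; evaluation is
   linear interpolation with linear extension beyond the fitted range.
   Saturated instances are excluded from fitting but kept for flag
   propagation.
3. **Duplicate averaging** — arithmetic mean of spot instances on the
   normalized linear scale, with per probe × array any-spot flags.
4. **QC filter** — probes saturated in any instance are removed first, then
   probes above background in no instance; the two categories are disjoint
   by that precedence and the retained count satisfies the conservation
   identity on every input.

Fitting and mapping happen in log2 because intensity noise is
multiplicative; the linear scale is recovered by exponentiation.

## Temporal differential expression

For each probe the values are log2-transformed and median-centered, and the
vector **d** of timepoint mean differences relative to the reference (3
hpf, the first sample) is modelled as a two-component multivariate-normal
mixture:

- null: **d** ~ N(0, σ²·C) with C = (I + J)/n the exact covariance induced
  by n replicates per timepoint and the shared reference mean (J the
  all-ones matrix — reference sharing itself creates autocorrelation);
  σ² is the probe's pooled within-timepoint residual variance shrunk 10%
  toward the across-probe average;
- differentially expressed: **d** ~ N(0, σ²·C + Σ₁) with Σ₁ a free signal
  covariance estimated from the data (posterior-weighted second moment
  minus the null part, projected to the nearest positive-semidefinite
  matrix), which lets temporally smooth signals carry autocorrelation.

The mixture weight and Σ₁ are estimated by EM (tolerance 1e-6 on the
weight, ≤ 200 iterations, initial weight 0.1); each probe's posterior
probability of the DE component is reported, and a probe is called
significant when (1 − posterior) < α with α = 0.01 — the probability-scale
reading of a p < 0.01 criterion. No multiple-testing correction is applied
by default (Benjamini–Hochberg is available as a helper). Probes with zero
residual variance are degenerate and get a missing posterior. A naive
per-probe one-way ANOVA across timepoints is provided as a comparator; on
null data its p-values are uniform and on mixed simulations its calls agree
closely with the posterior calls.

On all-null simulations the mixture is only weakly identified (any small Σ₁
with a matching weight fits); the EM weight can drift, but posteriors stay
below the 0.99 call threshold and the realized null call rate is ≈ 0.

## Clustering

Profiles are per-gene timepoint means over the four replicates, computed on
the log2 scale (so shape means fold change, not absolute intensity), then
within-gene z-normalized (population SD; constant rows become zeros and are
flagged degenerate — z-normalization is idempotent on the rest).

*K-means*: average-linkage hierarchical clustering on correlation distance,
cut at K, supplies deterministic starting centroids for standard K-means
(tolerance 1e-8, ≤ 300 iterations). This reading of "hierarchical K-means"
makes the result reproducible without multi-start.

*CAST*: pairwise affinity is (Pearson r + 1)/2, mapping the stated 0–1
affinity scale (raw-correlation mode available). The greedy loop opens a
cluster at the unassigned gene with the highest total affinity to the other
unassigned genes, alternately adds genes whose mean affinity to the cluster
meets the threshold (default 0.7) and removes members whose mean affinity
(self included) falls below it, closing the cluster when stable. At
termination every member's mean within-cluster affinity is ≥ the threshold.
Undefined correlations (constant profiles) map to affinity 0.5 and so fall
below the default threshold — a flat gene cannot join a correlation-defined
cluster, which is also why recovery benchmarks plant four *temporal*
archetypes (maternal, waves at 24 and 36 hpf, bimodal; maximum pairwise
profile affinity 0.58, safely below 0.7) rather than a flat class.

The maternal screen scores each gene's affinity to a strictly decreasing
reference ramp (z-normalized) and returns genes at or above the threshold.
Modality classification looks at local maxima above +0.5 z: qualifying
maxima at both the first and last timepoints → bimodal; otherwise the
dominant peak at the first timepoint → peak-at-start, elsewhere → unimodal
with its time; degenerate profiles → flat. The +0.5 z cut is a design
choice; the underlying study names bimodal genes without stating a rule.

## qPCR quantification

Standard curves are least-squares fits of Ct on log10(copies) over ≥ 3
distinct ten-fold dilution levels (simulated standards span 10¹–10⁷ copies
in triplicate); a non-negative slope is a calibration error. Efficiency is
E = 10^(−1/slope) − 1, so the canonical slope −3.3219 (= −1/log₁₀2) gives
E = 1.00, one doubling per cycle. Counts invert the curve,
copies = 10^((Ct − intercept)/slope); Ct values outside the calibrated
range yield counts with an extrapolation flag rather than an error, since
low-expressed transcripts sit near the detection limit. Counts are
expressed relative to ARNT2 (whose developmental expression is much more
stable than β-actin's) per sample; ratios are invariant to global sample
scaling, and replicate summaries report mean ± SD (median available).
Cross-platform concordance is per-gene Pearson r and a linear fit between
reference-normalized array and qPCR series, with r ≥ 0.9 as the default
concordance call — the underlying study reports "linear relationships"
without a numeric cutoff.

## Test and benchmark conditions

Problem sizes were chosen to characterize each stage precisely at desk
scale: normalization recovery uses 1000 flat probes with per-array warps
and spot noise only (σ_rep = 0, σ_spot = 0.05), so cross-array differences
isolate the planted warp — the criterion is median |Δlog2| < 0.1 against
the baseline. DE operating characteristics use 2000 probes per simulation:
type-I on all-flat data, power on 20% planted 2-log2 waves (detection at
posterior > 0.99), and call concordance (Jaccard) between the posterior
and ANOVA routes on a mixed simulation; these run on identity-warp data
feeding the DE stage's own input contract, isolating it from upstream
normalization error. Clustering recovery uses 400 genes from the four
separable archetypes, uncensored by the signal floor (see limitations),
scored by adjusted Rand index at zero noise and at σ_rep = 0.25. The probe
QC worked example runs at the full array scale of 21 893 probes. qPCR
checks are exact round trips at zero noise plus calibration accuracy at
σ_Ct = 0.15.

## Known limitations

- **Invariant-set normalization under asymmetric regulation.** When a
  large fraction of probes moves strongly in one direction (deep maternal
  decay by 48 hpf), rank matching between a late array and the baseline
  systematically selects probes whose noise compensates the global rank
  shift, biasing the curve by a shared array-level offset (up to ~0.4 log2
  under the default mix). Downstream, both the mixture model and ANOVA
  detect that shared shift on unregulated probes, inflating full-chain DE
  calls. This is a property of the method class, not an implementation
  artifact; analyses of heavily regulated designs should treat full-chain
  DE fractions with caution.
- **Floor censoring of deep decays.** The 5-unit floor truncates maternal
  profiles whose baseline is low, flattening their tails and splintering
  the maternal profile family; clustering benchmarks therefore run on
  uncensored profiles.
- **Curve edges.** The running-median curve is least constrained in the
  sparse intensity extremes; the linear terminal extension is a convention,
  and normalized values beyond the invariant range inherit its error.
- **Mixture identifiability.** On data with no true signal the DE
  component is unidentifiable; the posterior scale (though not the ≈ 0
  call rate) is then arbitrary.
- The real study's headline dataset results (e.g. its count of significant
  probes) require the deposited expression data and are out of scope here;
  the suite establishes correctness on synthetic ground truth instead.
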