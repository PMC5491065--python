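# Methods

This note records the statistical model, the numerical conventions, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Study design and data model

Three groups of single-channel arrays are compared: embryonic stem
cells (ES), otospheres (OS) and cochlear sensory epithelium (CSE). The
default layout is 15 arrays — 6 ES (two of them a technical-duplicate
pair, mirroring two newly hybridized samples alongside four public
ones), 6 OS and 3 CSE. An array is a vector of linear-scale
fluorescence intensities over ~60,000 regular probes plus a population
of negative-control probes that carry no complementary transcript and
therefore measure background.

An `ExpressionMatrix` carries provenance: a scale (linear / log2) and a
processing stage that may only advance through
`raw → background_corrected → normalized → filtered`. Operations check
the stage they require, which prevents, e.g., filtering a log2 matrix
against linear-scale thresholds.

## Preprocessing

**Background correction.** The default `normexp_moments` models each
array as observed = S + B with signal S ~ Exponential(α) and background
B ~ Normal(μ, σ²), estimated per array by the method of moments
(mean = μ + α, variance = σ² + α², third central moment = 2α³) and
returns E[S | observed], computed in log space for stability deep in
the background tail, plus an offset (default 16, a common variance-
stabilizing choice for single-channel data). When the moment estimate
is infeasible (σ̂² ≤ 0, which happens whenever the array's skewness
exceeds that of an exponential — including the heavy-tailed synthetic
arrays whose expressed signal is log-normal rather than exponential)
the array falls back to `subtract_floor` with a logged warning:
max(x − μ̂, 0.5) + offset, μ̂ being the array's negative-control mean
(or its 5th percentile when no control flags are available). Both
methods preserve within-array rank order. Parameter recovery of the
moment fit is verified on data actually drawn from the convolution
(α within 10% at 50,000 probes).

**Quantile normalization.** All arrays are forced onto the common mean
empirical distribution: the reference is the across-array mean of the
sorted columns; each value takes the reference value at its
within-column rank. Ties share the mean of the reference values over
their tied ranks, so after normalization the multiset of values is
*exactly* equal across columns — an invariant the tests assert with
bitwise equality.

**Negative-control filter.** Per array, the threshold is
1.10 × Q95(negative controls), Q95 interpolating linearly between order
statistics at position 1 + (n−1)p (numpy's default; the "95th
percentile" is convention-dependent, so the convention is fixed and
documented). "At least 10% brighter" is read multiplicatively with ≥ at
the boundary; a probe is kept iff it meets the threshold on at least
`min_arrays = 3` arrays. Filtering runs on the *normalized linear*
values (the filter is the last of the three preprocessing stages);
control probes are removed unconditionally. The filter is monotone: a
larger brightness factor or `min_arrays` can only shrink the kept set.

## Pattern model

For every probe of the filtered log2 matrix a classical one-way
fixed-effects ANOVA across the three groups gives
F = (SSB/(k−1)) / (SSW/(n−k)) and p from F(k−1, n−k). Degenerate
cases: SSW = 0 with SSB > 0 → F = ∞, p = 0; SSB = 0 → F = 0, p = 1.
The ANOVA uses all sample columns (technical duplicates enter as
samples); the *template-matching profile*, by contrast, averages
technical duplicates pairwise before the group mean, per the stated
duplicate-handling rule — for balanced pairs the two conventions
coincide.

Benjamini–Hochberg step-up converts p to q over all tested probes;
probes with q < 0.10 (default, configurable) are significant.

Each significant probe's mean profile (x̄_ES, x̄_OS, x̄_CSE) is
correlated (population Pearson, |r| capped at 1) against every
non-degenerate template:

* `binary6` (default): {0,1}³ minus the two constant corners — six
  patterns named ES high, ES and OS high, OS and CSE high, CSE high,
  OS high, ES and CSE high. With six templates the assigned probes
  partition exactly into the six groups.
* `ternary25`: {0,½,1}³ minus the two constant binary corners — 25
  patterns, of which the flat (½,½,½) has zero variance and is excluded
  from matching (24 matchable). Because Pearson correlation is
  affine-invariant, the 24 matchable templates fall into exactly 12
  equivalence classes of pairwise correlation 1; graded templates keep
  their own labels (reported as `graded:<name>~<nearest binary label>`)
  rather than being silently folded into the six binary groups.

The winner is the argmax correlation; exact ties (within 1e−12) prefer
binary templates, then the lexicographically smallest level vector, and
are logged. Constant profiles are unassignable and excluded from the
groups. Pattern assignment is invariant under positive affine
transformations of the profile, and complementary patterns (e.g.
(1,0,0) vs (0,1,1)) can never be confused because their correlations
with any profile have opposite signs.

**Fold change.** log2 FC = mean of the profile over the template's
1-axes minus the mean over its 0-axes (½-axes excluded). The baseline
is thus symmetric in the high/low axes, matching "upregulated in the
high groups" semantics; for templates lacking either extreme (possible
only in ternary mode) the fold change is undefined and reported as NaN.

**Gene filter.** Probes collapse to gene symbols by keeping the
max-|FC| probe per symbol (no collapsing rule is canonical; max-|FC| is
the common "most responsive probe" choice and is logged). A gene passes
with q < 0.05 and linear FC > 2 (log2 FC > 1), both strict.
Unannotated probes are retained under their probe id with a logged
count.

## Exploratory QC

PCA treats samples as observations and probes as variables, centered
and unscaled (the conventional default), via SVD of the centered
matrix; component signs are fixed deterministically (largest loading
positive). Sample correlation is plain Pearson over expression vectors.
Hierarchical clustering uses 1 − r distance with average linkage
(defaults; both configurable) and ordinary bootstrap probabilities:
probes are resampled with replacement and a node's support is the
fraction of resampled trees containing its exact leaf set. Multiscale
(approximately unbiased) bootstrap correction is deliberately out of
scope; plain bootstrap probabilities are reported. Marker z-scores use
the population (n) standard deviation per probe row, the common
heat-map convention; constant rows are zero-filled and flagged.

## qPCR arithmetic

Per sample ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean ΔCt
of the calibrator group; the relative quantity is 2^−ΔΔCt. Per-group
fold changes use the geometric convention 2^−mean(ΔΔCt) by default —
computed as a difference of group-mean ΔCt so the calibrator group's
fold is exactly 1 — with the arithmetic mean of relative quantities as
an option, since published panels rarely state which convention their
"mean of three experiments" uses. ΔΔCt is invariant to adding a
constant to every Ct of a sample. Technical-replicate wells are
averaged before ΔCt.

The Mann–Whitney U test returns U = min(U_a, U_b) with an exact
two-sided p (2 × the null CDF at U, capped at 1, from the exact
rank-split distribution computed by dynamic programming) for combined
n ≤ 20 without ties, and otherwise a normal approximation with
tie-corrected variance and no continuity correction; two identical
samples give p = 1 (the zero-variance case is handled explicitly).

## Synthetic data

The generator plants truth a scientist can score against. Per regular
probe and biological unit, true log2 expression = baseline (8.0) +
effect × (pattern level for the unit's group) + Normal(0, noise_sd);
arrays in a technical pair share the unit draw and add
Normal(0, noise_sd/2). Linear signal is 2^(log2 expression); observed
raw = signal + Normal(μ=50, σ=10) background, floored at 0. Negative
controls and an "unexpressed" probe fraction (5%) carry background
only, which is what the brightness filter should remove. Defaults —
60,000 probes, 500 negative controls, 100 probes per binary pattern,
effect 4 log2, noise sd 0.25 — are the package's standard study
conditions; the effect and noise levels correspond to a strongly
differential transcriptome where near-perfect recovery is the correct
expectation, and the monotonicity of recovery in effect size is checked
on a coarse grid (0.3, 1, 4).

What the generator does *not* emulate: probe-sequence and GC effects,
spatial gradients, saturation, dye chemistry, correlated noise between
probes of one gene, and any biological covariance structure beyond the
planted patterns. Passing recovery tests therefore demonstrates the
pipeline's correctness under its own model assumptions, not performance
on real arrays; the GEO series-matrix reader exists so users can run
the identical classification on deposited real data.

Annotation assigns one synthetic gene per probe and flags a 10% subset
with GO:0006351 to exercise the transcription-factor path. The TF
"refinement" step is modeled as an optional intersection with a
user-supplied TF catalogue (default off), since no fixed catalogue is
canonical.

All randomness flows from one `numpy` Generator seeded by the config;
identical configs produce byte-identical output files.

## Numerical choices and degenerate inputs

* Quantile convention: type-7 / 1 + (n−1)p everywhere a percentile is
  taken.
* Sums-of-squares tolerance in the ANOVA: 1e−12 absolute, on log2
  intensities of magnitude ~10.
* Tie tolerance in template matching: 1e−12 on correlations.
* Zero-variance guards: constant profiles are unassignable; constant
  samples get flagged NaN correlation rows; constant z-score rows are
  zero-filled.
* Matrix serialization uses shortest-round-trip float `repr`, so
  read∘write is the identity.

## Limitations

* Only the three-group one-way layout is supported; no moderated
  (empirical-Bayes) statistics, no covariates.
* The background-correction moment fit assumes an exponential signal;
  heavier-tailed arrays deliberately fall back to subtraction rather
  than returning a distorted fit.
* GO enrichment and any live annotation retrieval are out of scope;
  annotation is always a user- or simulator-supplied table.
* Bootstrap cluster support is the ordinary bootstrap probability,
  which is known to be conservative for small clusters.
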