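# Methods

## Experimental design and coding

A rotatable central composite design for k factors combines a 2^k factorial
at coded ±1, 2k axial points at ±α with α = (2^k)^(1/4), and replicated
center points, giving five levels per factor. Coded and real units are
linked affinely: one coded unit equals (axial_high − center)/α real units,
with the center at coded 0 and the axial extremes at ±α.

For the packaged two-factor experiment (ethanol 30–100% v/v centered at 65;
residence time 0–240 min centered at 120) the axial distance is fixed at
the two-decimal value **1.41**, not √2. This is deliberate: only 1.41
reproduces the published real levels at coded ±1 (40.2% ethanol, 34.9 min;
√2 would give 35.1 min). α is a configurable field of every factor scale.

The packaged design table stores run 2 at coded (−1.41, +1.0) exactly as
recorded, which is not a point of the standard 11-run CCD.
`CCDDesign.validate_standard` reports such departures without altering the
data, and `CCDDesign.as_standard` snaps each run to the nearest textbook
point (run 2 → (−1.0, +1.0)). The reproduction pipeline fits on the snapped
design: with the snapped coding all twelve packaged validation predictions
are matched to ≈0.25% and the nontransformed optimum's residence time to
0.1%, whereas the verbatim coding misses them by 8–13%. This indicates the
original regression software used the standard design matrix; we keep both
representations and make the choice explicit rather than silently
"correcting" the stored table.

## Response-surface model

The response model is always the complete six-term quadratic in coded
units, fitted by ordinary least squares; no term selection is performed.
With balanced replication the fit on run means equals the fit on all
replicates, so summary tables (mean ± SD, n) are first-class inputs.
Rank deficiency is detected before solving and reported with the collinear
columns named; at least six distinct design points are required.

## Adequacy ANOVA

Pure error pools within-group squared deviations over groups of
observations sharing the same coded point. With summary input this reduces
to between-center-run variation (df = 2 for three center runs); with
replicate-level input all within-point replication contributes. Lack of
fit is SS_residual − SS_pure-error and is compared to pure error by an F
test. Model adequacy is judged at a 90% confidence level by default and
genotype comparisons (Tukey) at 95%; both are parameters. When no point is
replicated the lack-of-fit test is reported as not testable rather than
approximated. An exactly interpolating fit can leave a lack-of-fit sum of
squares at rounding magnitude (≤1e−12 of SS_total); it is treated as zero.

## Tukey HSD and compact letters

The pooled within-group mean square is the replication-weighted average of
group variances, Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1); the critical value is the studentized
range quantile q(α; g, df) (scipy's `studentized_range`). Unequal group
sizes use Tukey–Kramer pairwise standard errors √(MS/2·(1/nᵢ+1/nⱼ)).
Letters come from the insert-and-absorb algorithm; letter order follows
descending means. With zero variance everywhere and equal means, all
groups share one letter.

## Canonical analysis and constrained optimization

The stationary point solves 2Bx = −g for the quadratic-form matrix B and
gradient coefficients g = (b₁, b₂); eigenvalues of B classify it, with a
relative tolerance of 1e−8 for declaring an eigenvalue zero (degenerate
surfaces return the ridge direction instead of a point). The experimental
region is the per-factor **box** [−α, +α]², not the α-radius disc: the
documented optima sit at coded corners with norm α√2, which only the box
contains. The box maximizer of a bivariate quadratic is found exactly by
case analysis — interior stationary point if concave and inside, otherwise
the best of the four edge-restricted univariate vertices and four corners —
so no iterative optimizer or mesh is involved.

Validation percent error is 100·|experimental − predicted|/predicted. The
predicted-value denominator was chosen because it reproduces the packaged
validation table's printed error column row by row, which the
experimental-value denominator does not. Improvement percentages compare
experimental validation means of each line against the control,
100·(line/control − 1), rounded half-away-from-zero to integers for
reporting. All printed values use round-half-away-from-zero (2 decimals for
g L⁻¹, 1 for percent), with full precision retained internally.

## Relative expression (2^−ΔΔCt)

ΔCt = Ct_target − mean(Ct_references) per sample; ΔΔCt subtracts the
calibrator group's mean ΔCt; fold = 2^−ΔΔCt. Averaging reference Cts
equals normalizing by the geometric mean of reference abundances (Ct is a
log₂ scale); this is the standard multi-reference convention and is the
default. Technical replicates are averaged per (sample, gene) before ΔCt;
biological replicates propagate to a group SEM of the fold changes. The
calibrator's *geometric* mean fold is exactly 1 by construction (its
arithmetic mean exceeds 1 under noise, by Jensen's inequality). The
calibrator group is a required argument — it is a biological choice the
data cannot reveal. Amplification-efficiency correction is out of scope.

## Off-target screening

Risk is summarized per candidate transcript by (i) the longest exact
identity stretch with the hairpin target window and (ii) the number of
distinct shared k-mers at the canonical siRNA length k = 21. Matching is
case-insensitive, U ≡ T, and N or any IUPAC ambiguity code never matches —
a conservative rule for off-target calling. Both subject strands are
searched by default because hairpins produce siRNAs from both arms; a
plus-strand match wins ties. The search builds a suffix automaton over the
query and streams each subject (linear in both lengths); its correctness
is defined by the O(nm) dynamic-programming recurrence, against which it
is tested on hundreds of random pairs. Coordinates are 1-based inclusive
throughout, with reverse-strand hits mapped back to original subject
coordinates.

## Synthetic data

Generators provide every input with known truth. CCD responses add i.i.d.
Gaussian replicate noise to a true quadratic surface — the packaged data
report means ± SD with no distributional information, so normality is a
documented modelling assumption, and the default noise SD of 1 g L⁻¹ with
4 replicates per run matches the magnitude of the packaged replicate SDs.
The default surface coefficients ("table1-like", b = 22.9, −7.8, 4.5,
−1.5, −2.6, −0.25) place the box argmax on the low-ethanol face near coded
time +1.2, mimicking the control genotype's geometry. Off-target sets
plant one copy of a query substring per subject, optionally broken by
SNPs, and rejection-sample the random background until no accidental
stretch exceeds the planted (post-SNP) truth. Ct tables encode requested
fold changes with per-sample loading drift (which ΔCt cancels) plus
optional per-well noise. All generators are bit-reproducible given a seed.

What the simulations do not emulate: heteroscedastic or correlated
replicate errors, run-order or block effects (visible in the packaged
center runs, whose spread the pure-error term absorbs), reference-gene
instability, qPCR efficiency below 100%, and homopolymer/repeat structure
of real transcript families. Passing recovery tests therefore demonstrates
correctness of the estimators under their stated assumptions, not
robustness to these real-data features.

## Problem sizes and numerical choices

Property suites use the 11-run design with 1–4 replicates, 500 simulation
seeds for parameter-recovery and noise-calibration checks, 201×201 grids
as optimization oracles, and random sequence pairs up to 600 nt against
the quadratic LCS oracle — sizes at which the independent oracles are
exact and fast. OLS uses `numpy.linalg.lstsq`; coefficient agreement with
explicit normal-equation elimination is asserted to 1e−8. Tie-breaking in
the box optimizer prefers the interior stationary point when it attains
the maximum; subject ranking in the screen breaks stretch-length ties by
k-mer count, then id.

## Known limitations

- Single response per fit: no multi-response desirability optimization.
- No weighted or mixed-effects fitting (plant vs technical replicates are
  pooled); the packaged tables' n = 4 is taken at face value.
- Off-target identity lengths from real paralog families depend on the
  transcript database version; the screen's published-style outputs are
  validated on synthetic families with planted truth.
- Only the box experimental region has an exact optimizer; the
  configuration schema reserves a sphere option, but no spherical
  optimizer is provided because the documented optima are infeasible on
  the α-radius disc.
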