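# Methods

## Model and assumptions

The package treats a biological system as *n* modules whose activities
reach a steady state, each summarised by one measured reporter. The core
assumption is local linearity around the basal operating point: small
relative changes of module activities are related by constant *local
response coefficients* r<sub>i,j</sub> (the direct effect of module j on
module i, normalised so r<sub>i,i</sub> = −1), and each elementary
perturbation q<sub>k</sub> touches only module k's intrinsic parameter.
Under these assumptions the observable *global* response matrix R and the
network satisfy r R = −P with P diagonal, giving the two-step solution
P<sub>i</sub> = 1/(R⁻¹)<sub>i,i</sub> and r = −[diag(R⁻¹)]⁻¹R⁻¹. After the
row-wise division the diagonal of r is set to exactly −1 rather than left
to floating-point rounding, so the normalisation convention is an
invariant of the data structure, not an approximation.

Relative changes are measured by the symmetric relative difference
2(x′−x)/(x′+x). It is bounded in (−2, 2) for positive abundances, is
antisymmetric under swapping its arguments, and never divides by a
near-zero basal value. Its inverse — needed to turn predicted relative
changes back into abundances — is implemented as x₀(2+v)/(2−v). An
algebraically equivalent rearrangement x₀(2/w−1)/(1+2/w) with w = −v
exists; the implemented form is preferred because it has no intermediate
division by a possibly tiny w, and the equivalence of the two forms over
(−1.9, 1.9) is asserted in the test suite to 1e−12.

Forward prediction under a combined perturbation with weight vector c is
v = −r⁻¹Pc; linearity between perturbation strength and parameter change
is assumed throughout, so fractional weights interpolate and weights sum.
Any predicted |v<sub>i</sub>| ≥ 2 cannot correspond to a positive
abundance and raises a saturation error naming the module instead of
returning a meaningless number.

## Replicate pairing and point estimates

With k_t biological replicates × n_r technical replicates, one R matrix is
computed per replicate slot: replicate (i, r) of every perturbed condition
is paired with replicate (i, r) of the basal condition, giving k_t·n_r
matrices (six for the default 3×2 design). Point estimates of r and P are
inferred from the element-wise *mean* of these matrices, not by averaging
per-replicate networks: r is a nonlinear function of R, and the bootstrap
is likewise centred on the mean R, so the point estimate and the interval
refer to the same quantity.

Inference refuses to proceed when cond(R) exceeds a threshold (default
1e8): inverting a near-singular response matrix silently amplifies
measurement noise into arbitrarily large coefficients, and an explicit
error with the condition number is more useful than such output.

## Variance from small replicate series (SPC)

Six replicates per cell of R are far too few for a per-cell sample
standard deviation of any stability. The package instead uses the
range-based estimator of statistical process control: within each
biological replicate (subgroup) take the range of the technical
replicates, average the ranges, and divide by Hartley's constant d2(n_r) —
the expected range of n_r i.i.d. standard normals (d2(2) = 1.128). This is
unbiased for normal data, respects the biological/technical hierarchy
(only intra-transfection spread enters), and its constants for subgroup
sizes 2–10 are embedded in the code. When a design has no technical
replicates (n_r = 1, e.g. duplicated RNA-seq runs), the biological
replicates themselves form one subgroup of size k_t — the only way to
obtain a range at all in that design.

For RNA-seq-style data with duplicates per gene, the per-cell estimator is
replaced by a pooled population estimate: all genes measured under the
same perturbation contribute their subgroup range, and the pooled mean
range is converted to σ via d2. Genes "out of control" are excluded
iteratively until the retained set is a fixed point, with the exclusion
threshold recomputed against the updated mean range each pass. The default
control rule is the standard range chart — exclude a gene whose range
exceeds D4(n)·(mean range), one-sided, since only excessive spread
invalidates pooling — with a ±3σ rule on the gene's mean response and a
rule-off mode as configurable alternatives; one-sided range-chart
exclusion is this package's choice among the standard SPC options, and
which rule a given analysis should use is left to the caller. The
iteration always terminates (the retained set strictly shrinks or the
loop exits) and errors out if fewer than a configurable minimum of genes
(default 5) remain, which signals a population too heterogeneous to pool.

## Parametric bootstrap confidence intervals

Intervals come from a parametric bootstrap on R, not on the raw data: each
draw samples every cell independently from Normal(mean_R[j,k], sd[j,k])
with cell-specific sd (cells of R genuinely differ in variance), runs the
exact inversion, and the CI of each parameter is the empirical percentile
pair (2.5th/97.5th at the 95% level) over draws. The default draw count is
one million; tests and the CLI quick profile use 10,000, which changes the
percentile estimates by far less than the interval widths at issue. A
coefficient is flagged significant exactly when its interval excludes
zero. Cells are drawn independently — no covariance structure is imposed —
and draws whose R is near-singular (1-norm condition estimate above the
threshold), or whose propagated relative change leaves (−2, 2) in
abundance prediction, are discarded and counted; if fewer than a
configurable fraction (default 50%) of draws survive, the computation
raises an instability error rather than reporting percentiles of a
mutilated sample. Identical seed and configuration give bit-identical
tables.

### Calibration benchmark

The coverage benchmark used in the acceptance suite draws one observed R
per dataset (R_true plus independent N(0, 0.05) per cell, 3 modules),
bootstraps at the generating sd with 10,000 draws, and measures how often
the nominal 95% interval covers each true coefficient over 500 datasets.
This isolates what the interval construction itself is responsible for —
the percentile machinery and the nonlinearity of the R→r map — and lands
at 93–97% per coefficient. Two neighbouring designs deliberately *not*
used as the benchmark: sampling the bootstrap at the replicate-level SPC
sd while centring on a 6-replicate mean targets single-measurement noise
and over-covers the truth by construction (≫ 98%); plugging in the
*estimated* sd of the mean adds estimator noise worth only ~2.6 degrees of
freedom at the 3×2 design, whose coverage deficit is a property of the
range estimator's variance, not of the bootstrap. Both variants remain
available through the `sd_source`/explicit-sd interface.

## Unidirectional MRA (udMRA)

A gene X never perturbed experimentally is appended as module n+1 with
outgoing coefficients fixed at zero (nothing constrains them) and incoming
coefficients solved from the exactly determined linear system
responses = coefficients · R — X's observed relative changes under the n
elementary perturbations expressed in the basis of the core modules'
responses. Prediction composes the core forward model with the fitted row:
u = coefficients · v, abundance = basal(2+u)/(2−u). Because the system is
exactly determined, the fitted gene reproduces its training responses
under elementary perturbations (an interpolation identity used as a test).

udMRA.ab additionally optimises the weights of the elementary
perturbations composing a combined one, on held-out observations of the
*core* modules: the objective is the summed squared relative error of the
core predictions (an absolute-error mode exists for near-zero
observations), minimised by a dense deterministic grid (step 0.05 over
[0, 2] per free weight) followed by Nelder–Mead refinement, with the full
evaluation trace recorded. With one or two free weights exhaustive search
is cheap, reproducible and free of local-minimum concerns; weights are fitted
once on the core modules and reused for all appended genes by default,
with a per-gene option. Naive baselines (mean, geometric mean, maximum of
the single-perturbation observations) operate on observed abundances by
default — the simplest reading of aggregating "the two knockdowns" — with
a fold-change-space option. The benchmark computes per-gene relative
errors |pred−obs|/obs and compares methods by a two-sided paired Wilcoxon
signed-rank test (sidedness is reported as such; identical methods return
p = 1 by convention since the statistic is undefined on all-zero
differences).

## Screening

Each candidate gene replaces one module's reporter: its response vector
overwrites that module's *row* of R (the other modules' responses to the
perturbations are unchanged), the network is re-inferred, and its distance
to the reference network is computed on the off-diagonal connection
coefficients flattened row-major — the fixed −1 diagonal is constant by
construction and would only dilute both metrics (a flag restores it for
parity experiments); P magnitudes likewise do not enter. Metrics:
Euclidean (ℓ2) distance and 1 − Pearson correlation. Candidates whose
assembled R is singular (e.g. a gene with zero response to every
perturbation) are recorded as un-screenable in a sidecar rather than
aborting the panel. Ranks are per metric, 1-based, with ties broken by
gene identifier so the ranking is independent of panel input order.

## Synthetic data generator

The generative truth is the linear local-response model itself: a drawn
(r_true, P_true) implies R_true = −r_true⁻¹diag(P_true), and noiseless
abundances invert the symmetric relative difference around known basal
levels. No ODE system is simulated — this matches exactly the structure
MRA can identify, which is the point of the fixture: the generator and the
inference core are exact inverses in the noiseless limit, and every other
guarantee is built on that contract. Random truths are rejection-sampled
to be well-conditioned (default cond(R) < 1e3) with all |R| < 2;
perturbation magnitudes default to negative (knockdown/ligand-removal
style), uniform magnitude 0.3–1.2; off-diagonal coefficients uniform
±0.6; basal abundances uniform 5–50 arbitrary units.

Noise has a biological component shared by the technical replicates of a
(condition, biological replicate) and an independent technical component;
the biological draw is per condition × replicate, since each
transfection/treatment well is an independent preparation (either sharing
convention is defensible; this one is documented as the implementation's
choice). Two spaces are supported: multiplicative log-normal on abundances
(default — the realistic error model for qPCR/RNA-seq-style measurements,
and deliberately *not* the model the bootstrap assumes, so tests exercise
mild misspecification) and additive Gaussian directly on R's entries
(matching the bootstrap's assumption exactly; per-cell replicate
distributions pass a seeded Shapiro–Wilk check at n = 1000). All
randomness flows from a single seed; equal seeds give byte-identical
datasets.

What the generator does not emulate: nonlinear saturation of real
dose–response curves, count noise at low expression, normalisation
artefacts across samples, and correlated noise between reporters measured
in the same well. Passing tests therefore certify the inference machinery
and its calibration under the stated noise models, not robustness to
those real-data effects.

## Problem sizes and numerical choices

The default test and acceptance workloads are: 200 random truths
(n ∈ {2..5}) for the noiseless round trip; 10,000 subgroups for the SPC
Monte-Carlo; 500 datasets × 10,000 bootstrap draws for coverage; 60 genes
for the udMRA benchmark — sizes chosen so the whole suite completes in
well under a minute on one CPU while keeping Monte-Carlo error far below
the asserted tolerances (the full-scale bootstrap default of 10⁶ draws
remains the library default). Tolerances: 1e−9 for end-to-end noiseless
recovery, 1e−10 for pure linear-solve identities, 1e−12 for algebraic
identities; cond thresholds 1e8 (inference guard) and 1e3 (truth
admissibility). Ties in screening rank by gene identifier; percentiles
use linear interpolation between order statistics (no BCa correction —
plain percentile matches the stated procedure).

## Known limitations

- Elementary perturbations must be truly elementary; off-target effects
  violate the diagonal-P structure and bias all coefficients.
- The bootstrap treats R's cells as independent; shared basal measurements
  induce correlation the intervals ignore.
- No topology selection: statistically insignificant edges are flagged,
  not pruned.
- The SPC population estimator assumes a common within-gene variance
  across the pooled population after exclusions; strong mean–variance
  coupling (untransformed counts) violates this and should be handled by
  variance-stabilising normalisation upstream.
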