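# Methods

## Switching model

A population of N cells contains R recombined and U = N − R unrecombined
cells. The mean recombined fraction under constant induction follows the
logistic curve

    f(t) = f_max / (1 + (f_max/f_0 − 1) e^{−k t}),

with f_0 the measured fraction at t = 0 (fixed, not fitted), f_max ∈
(f_obs,max, 1] the plateau, and k ≥ 0 the per-hour recombination rate. When
f ≪ f_max the leading term of the expansion in f/f_max is exponential
growth f_0 e^{kt}, which has one fewer parameter. Time is in hours, rates in
h⁻¹, inducer concentrations in molar throughout.

The stochastic generator is the pure-birth jump process R → R+1 at total
rate k·R·(1 − R/(f_max·N)), whose mean-field limit is exactly the logistic
curve — chosen so that parameter-recovery tests target precisely the model
the inference fits. A `constant_hazard` alternative (each unrecombined cell
switches at hazard k; mean 1 − (1−f_0)e^{−kt}) is provided as a mechanistic
contrast. N is held fixed during fraction simulation: with equal genotype
growth rates, growth cancels in the fraction; growth enters only the
plate-reader synthesis. Because the total rate depends only on R, the chain
is simulated *exactly* by drawing one exponential waiting time per state and
cumulating (vectorized next-reaction stepping); no tau-leaping approximation
is used. A start with round(f_0·N) = 0 is rejected for the logistic
mechanism (absorbing state; the mean curve divides by f_0).

## Measurement layers

**Cytometry.** Single-cell FL1-A is log-normal per genotype (defaults: dim
median 300 a.u., σ_log 0.5; bright median 30,000 a.u., σ_log 0.6 — about two
decades of separation, matching well-separated reporter populations); FSC-A
and SSC-A are shared log-normals. A configurable `immature_fraction` of
recombined cells reads out in the dim distribution, emulating cells that
recombined too recently to express and mature the fluorophore. True genotype
labels are retained as hidden ground truth for tests only.

**Gating.** Published gates for such data are drawn manually; the
reproducible surrogate here derives the gate from a control (dark) sample: a
debris cut at the control's 1st FSC-A percentile, then an FL1-A lower
boundary at tail quantile q (default 0.999) of FSC-passing control events,
optionally per FSC-A bin to allow a sloped boundary. By construction at most
1 − q of control events fall above the boundary. Fractions on the count
boundary (x = 0 or x = n) use the Jeffreys-style estimate (x+0.5)/(n+1) so
that downstream logistic fits (which divide by f_0) remain evaluable; the
binomial standard error is computed from the same point estimate.

**Plate reader.** Blank means are arithmetic averages over medium-only wells
per time step. The growth-normalized relative fluorescence is
r_i(t) = (F_i(t)/F_i(0) − F̄_b(t)/F̄_b(0)) / (OD_i(t) − ŌD_b(t)); the
endpoint variant replaces the numerator by F_i(t)/F̄_b(t) − 1. Time points
with blank-subtracted OD ≤ ε = 10⁻³ OD units are masked and flagged, never
silently zeroed — early-time 0/0 is expected in real plates. The
growth-rate estimate (maximum sliding-window slope of ln OD′, default 5
points) is a generic convenience, not an assay-defined statistic.

## Rate inference

The likelihood is binomial on gated counts, Σ x_i ln p_i + (n_i−x_i)
ln(1−p_i), when counts are available (they are, for cytometry data); a
Gaussian on fractions with per-point variance p̂(1−p̂)/n is the fallback.
The binomial form matches the measurement process and keeps AICc
comparisons principled. Degenerate predictions (p ∈ {0,1} against
discordant counts, or p > 1 from the exponential form) yield −∞.

The exponential fit maximizes over k ∈ [0, 10] h⁻¹ by a coarse grid plus
bounded Brent refinement (exact ties resolve to the grid point, so constant
data returns k̂ = 0 exactly). The upper bound 10 h⁻¹ is generous: it implies
saturation within minutes at these time scales.

The logistic fit uses an affine-invariant ensemble sampler (32 walkers,
2000 steps, 500 burn-in, seeded) under flat priors on [max measured
fraction, 1] × [0, 10]. Walkers start in a tight ball around a coarse-grid
likelihood maximum; at cytometry sample sizes the posterior is extremely
peaked, and dispersed starts strand walkers off the mode. Convergence is
checked with the split-chain Gelman–Rubin statistic (threshold 1.05) and the
point estimate is the maximum-likelihood posterior sample, so the AICc
comparison against the profile-maximized exponential fit is like-with-like.
If the f_max bound is empty (maximum measured fraction = 1) the fit
collapses to a one-parameter maximization with f_max fixed at 1.

Model choice per technical replicate: AICc = −2L + 2p + 2p(p+1)/(n−p−1),
lower wins; exact ties (|Δ| < 10⁻⁹) go to the exponential (fewer
parameters); zero-inducer replicates take the exponential unconditionally —
a flat series is explained equally by k = 0 at any f_max or f_max → f_0 at
any k, so the logistic parameters are unidentifiable there. Fits whose
maximum log-likelihood improves on the k = 0 constant model by less than
0.5 are flagged non-identifiable. Replicate ensembles report the pointwise
mean and min–max envelope of best-fit curves and k_min/k_mean/k_max.

A design caveat: when trajectories reach only ~10–15% of f_max within the
observation window, f_max itself is weakly identified and its
maximum-likelihood sample can wander over its allowed interval even though
k is recovered to within a few percent. f_max recovery is therefore only
asserted under saturating designs; in non-saturating regimes the AICc rule
hands the estimate to the exponential model anyway.

## Biosensor statistics

Detection uses two-sided Welch's t-tests between successive inducer
concentrations within each biological replicate, combined across
experiments per step with Fisher's method (X = −2Σ ln p ~ χ² with 2m df);
the lowest concentration whose step-up p falls below α = 0.05 is the
detection limit. No transformation is applied to readouts, and no
multiple-testing correction is applied across ladder steps (an optional
Holm flag exists, off by default). p-values are floored at 10⁻³⁰⁰, with a
warning, before logs.

A calibration caveat, measured by the validation studies: with only 3
technical replicates per group, Welch's approximate p-values are
non-uniform under the null (a single test rejects at ≈ 0.035 at nominal
0.05), and Fisher-combining three such conservative p-values compounds this
to a ladder type-I error of ≈ 0.030–0.035. The ladder is therefore
conservative, not anti-conservative, at these group sizes; exact
calibration to 0.05 would require Student's t (inappropriate under unequal
variances) or larger replicate counts.

Generation accounting: one cycle that dilutes a culture D-fold and regrows
it from density ρ_{i-1} to ρ_i contributes log2(ρ_i·D/ρ_{i-1})
generations. The printed form of this expression is typographically
ambiguous about division placement; the implemented convention makes the
carrying-capacity case (regrowth to the same density) equal exactly
log2(D), which reproduces the ~53-generation total of four 10⁴-fold
cycles. Both measured-density and dilution-only modes are exposed.
Stability tracking reports the relative change of the fluorescent fraction
versus the post-exposure reference; the deterministic two-type competition
recursion f′ = f(1−s)/(1−s·f) serves as the test oracle for
selection-driven decline.

## Synthetic-data scope

The generators emulate: inducer-dependent switching with logistic mean
dynamics; binomial/gate sampling noise of counted events; log-normal
single-cell fluorescence with an immature dim subpopulation; logistic bulk
growth with additive instrument noise and blank offsets. They do **not**
emulate: optical spillover/compensation, doublets, instrument drift,
day-to-day biological variability beyond what replicate seeds provide,
growth-rate differences between genotypes, or plate edge effects. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Validation studies use: 200 stochastic runs at N = 10⁵ for the generator
oracle (2% pointwise tolerance where f ≥ 10⁻³, below which Monte-Carlo
error dominates); a recovery grid k ∈ {0.05, 0.1, 0.2, 0.5, 1.0} h⁻¹ ×
f_max ∈ {0.5, 0.9} with 20 seeded datasets per cell, 7 time points over
8 h and 2×10⁴ events per point (pooled median |k̂−k|/k, dominated at the
low-k end by the information limit of ~20–30 events above baseline); 2000
null simulations for ladder calibration; 500 runs at 150,000 events for
rare-fraction detectability at true fraction 6.9×10⁻⁴. Global seeds fan
out to stages via `numpy.random.SeedSequence.spawn` in a fixed order;
seeded runs are bit-reproducible.
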