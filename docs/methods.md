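# Methods

This note documents the statistical models, the synthetic-herd generator,
the numerical choices, and the limitations of `pigquant`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The analysis problem

Behaviour indicators recorded under commercial farm conditions — backtest
struggling counts in piglets, handling and weighing scores at three ages,
skin-lesion scores before and after mixing — are ordinal and far from
Gaussian, yet they are routinely analysed with linear animal models. The
package implements both that linear analysis and the binary (logit
liability) alternative, the transformation that puts their heritabilities
on a common scale, and the cross-validation device used to compare the two
model families' ability to predict breeding values.

## Synthetic herd generator (`simdata`)

The generator emulates the design of the on-farm study whose published
variance components and score distributions serve as defaults: two genetic
lines, ~1,000 phenotyped fattening pigs descended from 31 boars and 135
sows, litters as the only family-environment grouping, and group-level
housing treatments.

**Pedigree.** `n_sires` and `n_dams` breeding animals, each dam one litter
(configurable) sired by a random boar, litter sizes Poisson with mean 7.44
(expected offspring count 135 × 7.44 ≈ 1,004; the litter-size distribution
is an assumption — the emulated study does not report one). `generation_depth`
adds founder ancestor layers above the parents (default 1); with depth ≥ 1
the parents are related, so offspring can be inbred and the A / A⁻¹ pair is
exercised with nonzero inbreeding. The default produces ~1,290 pedigree
animals; the emulated study reports 1,688 for 1,004 phenotyped pigs, but its
exact grandparental structure is not recoverable, so generation depth is a
parameter rather than a target.

**Trait model.** Per trait, the latent value is
`y* = mu + Σ fixed effects + litter + a + e` with `litter ~ N(0, σ²_le)`
shared within litter and `e` i.i.d. Gaussian (or logistic, for generating
data exactly under the logit liability model). Breeding values run down the
pedigree: founders `N(0, σ²_a)`; non-founders get the mean of their known
parents plus Mendelian sampling with variance `σ²_a (1 − 0.25 Σ(1+F_p))`
over known parents — consistent with the tabular A. Multi-trait runs draw
founder values and Mendelian deviations from a joint covariance built from
per-trait variances and user-specified genetic correlations; litter and
residual effects can be correlated the same way.

**Fixed effects.** Sex is assigned per animal (1:1); breed (19 % purebred),
rearing housing (3 classes), finishing housing (2 classes, 3:1) and the
unfamiliar-pig class (4 classes) are assigned at litter level, mirroring a
design where housing and mixing are group treatments. Default effect sizes
are modest fractions of the trait SD (0.1–0.36 SD). Batch/parity structure
is collapsed into litter identity, as in the models being fitted.

**Discretisation.** Ordinal scores and backtest counts are the Gaussian
liability cut at ordered thresholds. Thresholds are calibrated once per
trait: category probabilities come from a half-integer discretised normal
whose two free parameters are solved (least squares) so the discrete mean
and SD match the published phenotypic summary (e.g. piglet scale score
2.0 ± 0.8 on {1,2,3}); thresholds then sit at the corresponding quantiles
of the latent distribution, whose mean and variance include the
fixed-effect contribution under the default level frequencies. This keeps
realized score moments on target regardless of the genetic structure.

**Missingness.** Per-trait completely-at-random masking with rates taken
from the published per-trait record counts (e.g. 769/1,004 for the second
backtest). Masked cells are NaN, never sentinel numbers.

**Determinism.** One seed feeds a `SeedSequence` that is split per stage
(pedigree, factor assignment, genetics, trait noise, missingness), so the
pedigree realisation does not depend on which traits are requested, and a
fixed config + seed reproduces every byte.

**What the generator does not emulate** (so what passing tests do not show
about real data): maternal genetic effects, selection and non-random
mating, pen-level social interactions, batch/seasonal effects, age/weight
covariates at testing, informative missingness (real losses are mortality,
hence family-correlated), and any skewness of real score distributions
beyond their first two moments.

## Pedigree algebra (`pedigree`)

Validation topologically sorts the records (ties broken by input order, so
matrix indexing is reproducible), adds referenced-but-unlisted parents as
founders, and reports cycles and duplicates by animal id. A is built by the
tabular method; A⁻¹ by Henderson's direct construction with the exact
per-animal Mendelian-sampling variances (1, 0.75 − 0.25 F_p, or
0.5 − 0.25 (F_s + F_d)), i.e. inbreeding is fully accounted for — the
synthetic mating designs produce inbred animals and the A/A⁻¹ pair must
stay consistent. Unknown parents (empty field or "0") are base-population
founders. The test suite checks A against an independent recursive
coancestry oracle, A⁻¹ against dense inversion, and positive
semi-definiteness.

## Gaussian REML (`gaussian`)

The restricted likelihood is evaluated directly on the observed-record
scale: `V = σ²_a A_obs + σ²_pe PP' + σ²_e I` (A restricted to phenotyped
animals), `-2 rll = log|V| + log|X'V⁻¹X| + y'Py`. The maximiser is
average-information REML:

* Newton steps on **log-variances** (covariances on the raw scale in
  bivariate fits), so positivity is automatic; variances are floored at
  `1e-8 · var(y)` and flagged `boundary` there — published tables contain
  literal 0.00 components, so boundary estimates must be representable.
* Steps are damped (Levenberg-style) and only accepted if the restricted
  log-likelihood does not decrease, so the criterion is monotone along the
  accepted path; the first two univariate iterations use the classical
  EM-REML update `σ²ᵢ ← σ²ᵢ + (σ⁴ᵢ/qᵢ)(y'PVᵢPy − tr(PVᵢ))` for robustness
  far from the optimum, and EM is also the fallback when the AI matrix is
  unusable.
* Parameters pinned at the floor with an inward-pointing gradient are held
  out of the Newton system (active set); without this the clamped joint
  step stalls the free components on boundary rides.
* Convergence: maximum relative component change < 1e-8, cap 200
  iterations (both configurable). Non-convergence is flagged on the result,
  not raised.
* Standard errors: inverse average-information matrix at convergence;
  heritabilities and correlations get first-order delta-method SEs.
* Fixed effects: intercept plus treatment-coded factors (first observed
  level zero); any full-rank constraint gives identical REML components.
  Rank-deficient designs raise an error naming the confounded columns.

`reml_loglik_many` evaluates grids of component values, sharing one
factorisation across points that are positive multiples of one another
(the likelihood pieces scale analytically) — this makes the 11³
log-spaced-grid optimality check around each reported optimum affordable,
and that check is part of the acceptance suite.

**Bivariate fits** stack the two record vectors; V is linear in the nine
parameters (2 × additive, litter, residual variances plus the three
covariances). The residual covariance is estimated only when some animal
has records for both traits (otherwise it is not identifiable and is fixed
at 0). Each trait is internally scaled to unit variance for conditioning;
implied correlations are clamped to |r| ≤ 0.999 after every step (exact
r = 1 makes V singular — a trait paired with a copy of itself converges to
the clamp). A boundary additive variance marks the reported correlation
unreliable (it is still reported).

**BLUP.** Henderson's MME with `A⁻¹ σ²_e/σ²_a` on the animal block over the
*full* pedigree, so unphenotyped animals are predicted from relatives and
an animal with no information gets EBV exactly 0. The solution's relative
residual must be ≤ 1e-8.

## Threshold model (`threshold`)

**Recoding.** Published cut-points: load/scale scores 1 → 0, 2–3 → 1;
injection and lesion scores 1–2 → 0, 3–4 → 1; backtest counts ≤ 2 → 0,
≥ 3 → 1. Custom schemes must be total and order-preserving;
`median_split_cutpoint` picks the cut giving class proportions closest to
50:50 for arbitrary score distributions. Recoding followed by fitting is
invariant to monotone relabelings that preserve the cut.

**Likelihood.** Pr(y=1) = logistic(Xb + Pl + Za); the logistic residual
fixes the liability residual variance at π²/3 (reports print 3.29). With a
single binary record per animal, a Laplace approximation over *all* random
effects collapses σ²_a severely (the well-known small-cluster bias: on
simulated herds of ~2,000 the profile of that approximation peaks near
0.1–0.3 when the generating value is 1.0). The estimator therefore
exploits the animal-model structure: for every **terminal** animal
(phenotyped, childless — the typical fattening pig), the observation's
marginal likelihood given its parents' breeding values and litter effect
is a one-dimensional integral over its Mendelian-sampling deviation,
computed exactly with 31-node Gauss–Hermite quadrature; the Laplace
approximation is applied only to the remaining latent vector (fixed
effects under a flat prior — the binary analogue of REML —, litter
effects, and breeding values of non-terminal animals), each element of
which aggregates several-to-many observations. A phenotyped animal that is
itself a parent simply stays latent (its quadrature is degenerate at
τ = 0), so arbitrary pedigrees are handled. The outer maximisation over
(log σ²_a, log σ²_pe) uses Nelder–Mead with warm-started Newton
mode-finding; the admissible range is [1e-6, 50] and estimates at either
end are flagged `boundary` (a likelihood that is flat in σ²_a — no family
structure — can drift to the ceiling, because infinite liability noise
attenuates every probability to the base rate). Standard errors come from
a central-difference observed-information matrix on the log scale, mapped
back by the delta method. Separation (a fixed-effect level with a constant
response) is detected and flagged, not raised.

EBVs: non-terminal animals take their posterior-mode values; a terminal
animal gets its parent average plus the posterior mean of its Mendelian
deviation, `τ² d/dc log p(y|c)` at the mode. EBVs stay on the liability
scale (the cross-validation compares correlations, which are scale-free).

**Gibbs reference.** An independent Pólya-Gamma Gibbs sampler over the
exact observation-level model (all breeding values latent): PG(1, η)
mixing makes the coefficient update jointly Gaussian and the variance
updates inverse-gamma (unit-scale IG(2, 1) priors — weakly informative on
the liability scale, where components are O(1)). PG draws use the
truncated infinite-series representation with 200 terms; the truncation
biases the PG mean by ~1/(2π²·200) ≈ 0.1 %, far below Monte-Carlo error at
the few-hundred-animal scale where the sampler serves as the slow,
auditable cross-check of the deterministic path. Whether the litter effect
is integrated or conditioned on is thereby explicit: both paths integrate
it (the Gibbs sampler by sampling, the fast path by Laplace).

## Scale transformation (`transforms`)

h²_liab = h²_obs · p(1−p)/z², z = φ(Φ⁻¹(1−p)); the pair of functions is an
exact inverse pair, symmetric in p ↔ 1−p, with the observed→liability
multiplier minimal (π/2) at p = 0.5. The relation is defined on a *normal*
liability; applying it to heritabilities from a logistic-link model — as
the pipeline's `h2_tr` column does, at the realized incidence — is the
conventional approximation and is flagged here explicitly. Published
transformed-h² columns for this kind of data cannot generally be
reproduced from the printed components because the incidences actually
used are unpublished and the transformation direction is ambiguous; some
rows are consistent with observed→liability at plausible incidences and
others are not at any incidence. The pipeline therefore computes
observed→liability from its own realized incidence and makes no claim of
matching published transformed values. A transformed value above 1 warns
(the input is inconsistent with a threshold model at that incidence) but
the mathematics is not clipped; clipping is a reporting concern.

## Cross-validation (`crossval`)

Balanced random folds (sizes differ by ≤ 1; 1,004 animals at k = 4 give
251 per fold), repeated with fresh partitions; per fold, the trait's
phenotypes of the fold animals are masked — the animals always stay in the
pedigree — and EBVs at fixed components are recomputed, then correlated
with the full-data EBVs over the fold's animals (all of them: fold members
without records are never dropped, their EBVs exist in both runs). Whether
components are re-estimated per training set is a switch
(`refit_components`, default off: estimated once on the full data, cheaper
and stabler; re-estimation is a defensible alternative reading of the
procedure). A fold whose refit fails yields a missing correlation, warned
and excluded from the summary.

**What the measure captures.** For nested BLUPs at fixed components the
correlation between full-data and masked EBVs equals
√(rel_masked/rel_full) — the share of EBV accuracy retained when own
records are dropped. It is a model-agreement / information-retention
measure, *not* a signal detector: it does not increase with heritability
(both reliabilities grow together), and it stays high even for pure-noise
phenotypes, because full and masked EBVs share the relatives' records that
dominate both when the own-record weight is small. The package reports the
comparison between model families and does not hard-code any expected
direction; on real data either family may come out ahead. For validating
against simulation truth, correlate masked EBVs with
`Herd.true_breeding_values` instead.

## Reporting (`cli`)

Human tables round to 2 dp (the threshold residual column is headed by the
constant 3.29); machine-readable files keep full precision. A trait fitted
on one scale only leaves the other block blank, never zero. Every artifact
is stamped with the resolved seed and a hash of the resolved config; the
run log carries seed, hash and stage timings, and no numeric result exists
only in the log. Identical config + seed reproduce all numeric outputs
byte-identically (the log differs in timings only). Per-trait failures are
isolated and recorded in `status.tsv`; input problems (missing trait
columns) abort before any fitting.

## Test problem sizes

Chosen so the default suite runs in minutes while keeping each check
informative: univariate Gaussian recovery uses 20 replicates of the full
31 × 135 herd (~1,000 offspring) at the second backtest's component values
(0.52, 0.08, 0.87), with an 11³ grid-optimality check per replicate;
binary recovery uses 20 replicates of ~2,000 pigs at liability components
(1.0, 0.3) with median-split binarisation; the Gibbs agreement check uses
one ~300-animal herd and 1,500 sweeps; bivariate correlation recovery uses
5 replicates of ~500 pigs (r_g = 0.8) plus 5 independent-trait replicates,
with tolerances widened accordingly; cross-validation checks use the full
herd with 5 repeats × 4 folds.

## Known limitations

* The threshold-model fast path is approximate; its residual downward bias
  on σ²_a (a few tens of percent in h² terms at n ≈ 2,000 with this family
  structure, as measured by the recovery suite) is inherent to
  Laplace-type approximations for binary data and shrinks with family
  size. The Gibbs path is exact but slow and prior-dependent.
* Single binary records per animal identify liability variances weakly;
  expect wide standard errors and occasional boundary estimates at
  study-scale n.
* No maternal genetic effects, random regression, > 2-trait fits,
  dominance/epistasis, genetic groups, marker-based relationship matrices,
  or probit links (the fixed 3.29 presumes logistic residuals).
* Dense linear algebra throughout; comfortable to a few thousand records
  and pedigree animals, not designed for national-evaluation scale.
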