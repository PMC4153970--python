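# Methods

`cogirt` couples item response theory (IRT) with pharmacometric
latent-variable modelling for the ADAS-cog, the 11-13 component cognitive
assessment used as the primary endpoint in mild-to-moderate Alzheimer's
disease trials. This note documents the models, the numerical choices, the
synthetic-data generator, and the limits of what the test suite
demonstrates.

## Latent scale and item models

All item outcomes are driven by a single latent *cognitive disability*
`D`, standardized to N(0, 1) in the cross-sectional reference population
(this convention fixes the location and scale of the otherwise arbitrary
latent axis; larger `D` = worse cognition). Five model families cover the
mixed item formats:

| family | outcome | model |
|---|---|---|
| `binary3pl` | pass/fail task | P(fail) = c + (1-c)·expit(a(D-b)) |
| `binomial_words` | word-recall errors of n words | Binomial(n, p) with the 3PL p |
| `word_recognition` | recognition errors | Binomial(n, p), p = c + (d-c)·expit(a(D-b)); optionally renormalized over a truncated stored range (e.g. 0-12 of 24 scored words) |
| `gen_poisson_count` | number-cancellation points (0-40) | generalized Poisson with mean bound d, mean p(D) = d·(1 - expit(a(D-b))), dispersion δ, renormalized over the bounded support |
| `ordered_categorical` | examiner rating, 5 categories | proportional odds on cumulative logits, non-decreasing thresholds |

Notes on the generalized Poisson: the count support is bounded, so the pmf
is renormalized over 0..40 (the printed normalizing factor in the source
model is read as this truncation; any other reading cannot keep the score
in range). Validity requires p(D) + δk > 0 on the whole support, and the
dispersion is constrained to the classical |δ| < 1 range during
estimation. The mean bound `d` is likewise constrained to the count
support (`d` ≤ 40): without these constraints the truncated likelihood has
a near-flat ridge on which `d` and δ can drift to meaningless values.

All pmfs and their analytic derivatives with respect to `D` are computed in
log space; probabilities are clipped at 1e-12 from the boundaries so that
extreme parameter proposals during optimization produce finite (if tiny)
likelihoods rather than NaN gradients.

## Baseline (cross-sectional) estimation

`BaselineIRT.fit()` maximizes the marginal likelihood with `D` integrated
out. The default integration is fixed-grid Gauss-Hermite quadrature with
41 standard-normal nodes (Bock-Aitkin marginal maximum likelihood); with
the latent prior pinned at N(0, 1) this is the standard IRT approach, and
it permits a table-lookup vectorization over subjects. Per-subject Laplace
and adaptive Gauss-Hermite are available both as fit methods and through
`marginal_loglik_subject` (the Laplace option mirrors classical NONMEM-style
estimation; at 40+ items per subject the two agree to a fraction of a
percent, which the tests check against a 20,001-point dense-grid oracle).

Parameters are estimated on transformed scales (log discrimination, logit
asymptotes with c < d enforced by construction, ordered thresholds as first
threshold plus log-increments) with box bounds acting as sanity rails
(|b| ≤ 6 latent SDs, a ≤ 20). The optimizer is L-BFGS-B with an exact
objective and a forward-difference gradient that exploits separability:
perturbing one item's parameter only changes that item's likelihood rows,
so a full 66-parameter gradient costs about two objective evaluations.
Items with degenerate response patterns (all-minimum or all-maximum) or
fewer responses than `min_subjects_per_item` are held at their starting
values with a named warning. Starting values are a = 1, b = 0, c = 0.05,
d = 0.95 (recognition) / 30 (counts), δ = 0, thresholds equally spaced on
[-1, 2]; all overridable.

Standard errors are available on demand (`asymptotic_se`) from a
finite-difference observed-information matrix, delta-methoded to the
natural scale. The 3PL lower asymptote deserves a warning that the
information matrix makes precise: with ~2,000 subjects, single binary
tasks identify `c` and `a` only weakly (SE(a) ≈ 0.1-0.3), because the
asymptote and the slope trade off. Recovery tests therefore use tolerance
floors of three asymptotic SEs; word-count and rating items, which carry
many Bernoulli trials or categories per administration, are far better
identified.

Empirical Bayes disability estimates (`estimate_ebe`) are posterior modes
with curvature SDs; subjects without records fall back to the prior
(0, 1) with a warning.

## Longitudinal progression model

`LongitudinalIRT` keeps the item (ICC) parameters fixed — typically at
previously estimated baseline values — and models each subject's latent
trajectory linearly in time,

    D_i(t) = (θ1 + η_i1) + (1 - β·x_i) (θ2 + η_i2) · t,

with correlated bivariate-normal random effects (SDs ω1, ω2, correlation
ρ), time in months at every interface and years internally (rates are per
year), and an optional fractional slope reduction β in the treated arm
(x_i = 1), entering multiplicatively on the full random slope. Linearity
is justified when total change over a 1.5-2 year trial is small on the
latent scale.

Dropout is interval-censored: a subject who leaves is only known to have
done so between the last attended and first missed scheduled visit
(contribution S(t_last) - S(t_missed)); completers contribute S(T) at the
last scheduled visit. Four log-linear hazards are supported — constant,
current-disability, progression-rate and baseline-disability dependent —
all with closed-form cumulative hazards (the current-disability hazard is
the exponential of a linear function of time, so its integral is closed
form as well; a dense Riemann-sum oracle verifies it). Hazard selection
uses the likelihood-ratio test against the constant hazard at 5% with 1
df, with each expansion warm-started from the constant-hazard optimum so
the LR statistic cannot go negative beyond optimizer slop.

### Marginal likelihood engine

The per-subject likelihood integrates the two random effects. Because the
item parameters are fixed, the per-(subject, visit) data log-likelihood as
a function of the latent value does not depend on the population
parameters; it is pre-tabulated once per dataset on a dense latent grid
([-8, 8], step 0.05) together with its analytic first derivative, and
interpolated with cubic Hermite polynomials during optimization. One
marginal-likelihood evaluation then reduces to a vectorized 2-D Newton
search for each subject's conditional mode (monotone damped Newton with
per-subject backtracking, converged to gradient norm 1e-8, with a
deterministic cold restart for any subject that fails) followed by the
Laplace approximation (default, the classical pharmacometric choice) or
adaptive Gauss-Hermite quadrature (n×n nodes) around that mode. Tight
inner convergence matters: the outer optimizer differentiates the marginal
likelihood with ~1e-8 finite-difference steps, so the inner solution must
be reproducible well below that scale.

The outer optimization is L-BFGS-B on transformed parameters (log ω,
atanh ρ); standard errors come from a central-difference Hessian with a
deliberately large step (0.02 on the transformed scale — the curvature in
the drug-effect direction is small and a naive 1e-4 step is dominated by
evaluation noise, producing badly anti-conservative SEs). Wald confidence
intervals on β give the drug-effect test. When variance components sit on
their boundary the information matrix is singular; SEs are then salvaged
from the identified submatrix and the boundary parameters reported as NaN.

At trial scale (200-400 subjects, 7-8 visits, the 21-item reduced bank) a
full fit with SEs takes well under a second, which is what makes the
simulation studies below practical on one CPU. Against a 401²-point 2-D
dense-grid oracle the adaptive quadrature agrees to 1e-6 on toy subjects;
against the exact per-subject reference implementation
(`joint_subject_loglik`, no interpolation) the engine agrees to ~1e-5
relative.

## Fisher information and sub-test ranking

Because `D` is the only random quantity, the Fisher information of an item
is I(D) = E[(∂ log P(Y|D)/∂D)²], evaluated exactly from the analytic score
over each item's bounded support. This single expression reduces to the
textbook forms (p'²/p(1-p) for binary items, n times that for binomial
counts, Σ P_k'²/P_k for ordered categories) and covers the truncated and
generalized-Poisson families where no closed form is printed; a
finite-difference oracle verifies it to 1e-5 relative. Information is
additive over items. Population-average information integrates I(D)
against a user-supplied Normal(mean, sd) disability distribution by
Gauss-Hermite quadrature (41 nodes); component information sums its items,
and `rank_components` produces the descending ranking with
percent-of-total, ties broken alphabetically. The MCI / mild-AD population
means and SDs are inputs — they are estimated quantities of a specific
cohort and are not hard-coded.

## Synthetic data generator

The generator is first-class, tested code and defines the study conditions
for every experiment in the package:

- **Multi-study baseline data** (`simulate_baseline_studies`): 2,744
  subjects across eight studies by default, with per-study assessment
  variants (additional delayed-word-recall / number-cancellation
  components, excluded naming/recognition components, a variant storing
  recognition errors truncated at 12 of 24 scored words, and a variant
  administering recognition three times with separate parameters) —
  roughly 100,000 item records with the default bank. `D` ~ N(0, 1) per
  subject.
- **Longitudinal trials** (`simulate_trial`): correlated random effects
  from the bivariate normal, arm-specific slopes, item sampling at every
  attended visit, and inverse-CDF dropout times from the subject-specific
  survival function when a hazard is given (no dropout otherwise —
  matching the no-dropout convention of the power studies).

The committed default bank (`default_bank.yaml`) is a hand-authored,
plausible 13-component bank — explicitly NOT estimates from any published
analysis. Its ICCs are shaped to the field's qualitative facts: binary
task items peak to the right of the reference population, delayed word
recall is steep and informative at low disability, rater items carry
little information, recall repetitions get easier for healthy subjects. A
21-item `reduced_bank()` covering all five families is used where runtime
matters more than breadth. The default progression parameters used
throughout the trial experiments are θ1 = 0.95, θ2 = 0.35/yr, ω1 = 0.68,
ω2 = 0.39, ρ = 0.54, with a 20% slope reduction (β = 0.2) as the reference
drug effect — the reported LEADe-population estimates, used here as
simulation truth.

What passing tests on these data do **not** show: real ADAS-cog data have
rater effects, practice effects, non-ignorable dropout, model
misspecification and item-parameter uncertainty, none of which the
generator emulates. Recovery results demonstrate the estimator is
consistent and calibrated under its own assumptions, not that the model
fits any particular trial.

### Total-score map

The scoring arithmetic of the ADAS-cog is configuration, not code: the
default map implements the familiar conventions (word recall = rounded
mean errors over three trials, 0-10; recognition 0-12; task components =
failure counts; rater items their category; number cancellation binned
from points scored to 0-5) and is fully overridable in the bank YAML.
Rater items have five categories (0-4), so the default 11-component total
has a maximum of 66 rather than the nominal 70 — the map maximum derives
from the bank rather than being asserted. Partially missing components
are prorated to the subject's administered item count by default.

## Comparator analyses

- **LS-means**: change from baseline ~ treatment + visit +
  treatment-by-visit + baseline score, subjects as grouping factor (random
  intercept = compound symmetry, the stable choice at trial sizes; a
  random-slope relaxation is available), fitted by REML via statsmodels
  MixedLM; the decision reads the treatment contrast at the last scheduled
  visit. Without dropout this is the MMRM analysis. The fixed-effect
  contrast is cross-checked against R's `nlme::lme` in the test suite.
- **Total-score progression model**: Score = (B + η_B) +
  (1 - β·x)(S + η_S)·t + ε with correlated random effects and additive
  residual — a reconstruction of the standard pharmacometric linear
  disease-progression analysis of the summary score; the marginal
  per-subject distribution is multivariate normal, so the likelihood is
  evaluated in closed form grouped by arm and visit pattern. Totals are
  analyzed untransformed, deliberately mirroring common practice.

Both declare significance when the 95% Wald CI of the effect excludes the
null, as does the IRT analysis.

## Power and type-I studies

`power_study` simulates each replicate trial once and analyzes it with all
requested methods (common random numbers — this sharpens between-method
comparisons; reported per-method powers are unchanged in expectation).
Per-replicate seeds derive deterministically from the master seed. Fit
failures default to "non-significant" (conservative); Wilson intervals
accompany every rejection rate. `subjects_for_power` interpolates a power
curve after an isotonic (pool-adjacent-violators) fit to remove
Monte-Carlo jitter.

Problem sizes used by the replication suite (chosen to keep the full suite
desk-scale on one CPU): 10 replicates for the 322-subject longitudinal
recovery, 40 for the 400-subject drug-effect recovery, 300 null trials at
200 subjects for type-I calibration, and 200 shared replicates per sample
size (200 and 400) for the power ordering, all with the reduced bank
except the LEADe-scale recovery, which uses the full default bank's
11-component variant.

## Diagnostics

`icc_vs_smoother` compares a fitted ICC with a penalized cubic B-spline
GAM of observed outcomes against the empirical Bayes disability estimates
(logit link for binary outcomes, GCV-chosen smoothness, pointwise 95%
band, optional per-study stratification). `vpc` produces simulation-based
predictive-check bands at three levels — per-item outcome fractions,
total-score median and outer percentiles per visit, and the retention
curve — as 2.5/97.5 percentiles across replicate simulations (percentile
method, no band smoothing; default 200 replicates).

## Known limitations

- One latent dimension; no covariates on `D`; no nonlinear progression
  shapes; no intermittent (non-monotone) missingness; no prediction-
  corrected VPC.
- Laplace integration is approximate for subjects with few informative
  items; the quadrature options exist for exactly that reason.
- Published item estimates and cohort disability distributions are not
  bundled; reproducing published component rankings requires transcribing
  the supplementary estimates into a bank file
  (`load_supplementary_bank`) and supplying the population moments.
- The printed dropout-hazard estimates of the source study (1.68, 0.65)
  are not reproduction targets: their units/parameterization are not
  inferable from the text, and under the formula as printed they imply an
  implausibly high yearly hazard; the hazard machinery is instead
  validated by self-consistent simulation and recovery.
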