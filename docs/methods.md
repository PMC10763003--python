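# Methods

This note documents the statistical machinery in `prsval`, the modelling
choices behind the synthetic-data generator, and what the package's tests
do and do not establish about real data.

## Study design being modelled

The target design is a nested case–control study inside a prospective
cohort followed by biennial questionnaire. Incident cases are identified
at 2-year cycle resolution; for each case, m controls (default 2) are
drawn by risk-set sampling from subjects still event-free at the case's
diagnosis cycle, matched exactly on year of age. A subject sampled as a
control may later be diagnosed and re-enter as the case of a later set —
this is a property of risk-set sampling, not a defect, and the generator's
tests assert that it occurs. Each subject serves as a control at most
once, so the control series consists of distinct women (m × n_cases when
no sets are dropped). Cases with fewer than m eligible age-matched
controls are dropped and counted; no age caliper is applied.

## Synthetic-data generator

The generator exists so that every downstream stage is testable without
access to individual-level cohort data. It emulates:

- **Genotypes**: `Binomial(2, f)` per variant with frequencies drawn from a
  configurable range; with two subpopulations, frequencies are shifted
  apart by a divergence parameter so that ancestry PCA has structure to
  recover. Variants are independent given subpopulation — there is no LD,
  no haplotype structure. This suffices for scoring, pruning and PCA
  mechanics but says nothing about panels whose information is spread over
  correlated variants.
- **Covariates**: nine binary indicators patterned on the epidemiologic
  risk-factor table of such studies (family history of breast and prostate
  cancer, early menarche, breastfeeding, ≥5 years of oral-contraceptive
  use, bilateral oophorectomy, adolescent and current high BMI, breast
  biopsy), with control-like prevalences.
- **Events**: per-cycle probability = age-specific 2-year baseline
  (derived from a 5-year incidence table via `1 − (1−ρ)^{2/5}`) times
  `exp(lp)`, where `lp` is the log-additive covariate + PRS predictor
  centred so the cohort-average relative risk is 1. There is no competing
  mortality.
- **Questionnaire risk**: 5-year absolute risk computed from the
  covariates only (never genotype) as `ρ(age) · exp(lp_q) / E[exp(lp_q)]`,
  evaluated at the index age when a matched study is drawn. Because
  genotypes and covariates are independent, the correlation between the
  questionnaire risk and the PRS is near zero by construction (~|r| < 0.05
  at n = 10,000), matching the near-independence such studies report.
  The questionnaire coefficients can be scaled away from the true ones to
  create misspecification scenarios.
- **ER subtype**: events are labelled unknown with probability 71/922 and
  otherwise ER-positive with probability 555/851 ≈ 0.652, the typed case
  mix of the motivating validation series.
- **Missingness**: MCAR masks covariate cells uniformly; MAR conditions on
  case status (cases masked at a configurable multiple of the control
  rate). Design fields (case status, set id, age) are never masked.

### Signal calibration

Defaults are fixed to the published discrimination levels of this kind of
analysis and are not tuning knobs:

- `prs_effect = ln(1.42)` per (population) SD of the PRS — the per-SD
  odds ratio reported in external validation of an African-ancestry PRS.
- Covariate effects are scaled so `var(lp_cov) ≈ 0.071`; for a normal-ish
  score with variance σ² entering a rare-outcome logistic model, the
  case–control shift is ≈ σ², giving a matched AUC of about
  `Φ(σ/√2) ≈ 0.575` for the questionnaire score, ≈0.59 for the PRS, and
  ≈0.62 for their combination — the 0.577 / 0.584 / 0.623 pattern of the
  motivating study.
- Default cohort scale (15,000 subjects, 12 cycles; 35,000 at acceptance
  scale) yields on the order of 900–2,500 matched sets, bracketing the
  922 sets of the real analysis. The default panel size (300–500 variants)
  is a computational stand-in for the tens of thousands of variants in
  real panels; scoring is linear, so panel size affects only the weight
  granularity, not the pipeline's behaviour.
- Subtype weight panels are mostly disjoint with a ~1.4% shared core,
  following the published panel composition (29,299 ER+ and 28,392 ER−
  variants whose union is 56,920).

A single global seed fans out to per-stage generators through a fixed
splitting rule (`seed · 1000003 + crc32(stage)` mod 2³¹−1), so individual
stages are reproducible in isolation.

## PRS construction

Scoring is `score_i = Σ_j w_j d_ij` after allele alignment: variants whose
counted allele equals the panel's other allele contribute `2 − d`;
strand-ambiguous A/T and C/G pairs cannot be oriented from alleles alone
and are retained with a warning (dosages presumed pre-harmonized; a strict
mode drops them); disjoint-allele variants are excluded and block scoring
until resolved. Missing dosages default to the expected count 2f from the
observed frequency. The default imputation-quality threshold is 0.3
(configurable; the INFO-vs-r² distinction is immaterial to the mechanics).

Subtype combination is the case-mix-weighted average
`prop_pos · PRS_pos + (1 − prop_pos) · PRS_neg` of the *raw* subtype
scores; whether the published score standardized each subtype first is
not documented, so pre-standardization is available but off by default.

Standardization and percentile categories both use the **control**
distribution: z-scores in control-SD units, categories from empirical
control quantiles (linear interpolation) with half-open intervals — a
score equal to a boundary falls in the upper band. The control SD is used
as the per-SD unit because the percentile bands are explicitly
control-based and the two conventions should agree.

Ancestry PCA filters on MAF ≥ 0.02 and missingness ≤ 0.5%, then greedily
prunes in input order keeping variants with pairwise |r| ≤ 0.1 against all
previously kept ones (deterministic; the order-dependence mirrors common
practice), centres at 2f, scales by `√(2f(1−f))`, and takes the top-k left
singular vectors. Component selection fits one joint logistic model of
case status on all k components and keeps those with Wald p < 0.05.

## Conditional logistic regression

For sets with one case and m controls the conditional likelihood is
`Σ_s [x_case·β − log Σ_{j∈s} exp(x_j·β)]`, free of per-set intercepts.
The solver is Newton–Raphson with analytic gradient (case covariates minus
within-set softmax expectations) and Hessian (negative sum of within-set
covariance matrices), step-halving on likelihood decrease, convergence at
gradient max-norm < 1e−8, max 50 iterations, covariance from the inverse
negative Hessian. Per-set softmax terms are max-shifted for overflow
safety. Columns constant within every set are rejected as unidentifiable;
coefficients drifting past |β| > 15 with a vanishing gradient are reported
as separation. With one case per set there are no within-set ties to
break. Wald 95% CIs use z = 1.959964. Unconditional logistic regression
(PC selection, reclassification models) delegates to statsmodels' Logit;
the in-package conditional solver is cross-checked in tests against
statsmodels' independent ConditionalLogit implementation.

## Matched discrimination and the combined score

The matched c-index is the fraction of within-set (case, control) pairs
with `score_case > score_control`, ties ½. It is invariant to strictly
increasing transforms (hence the log transform of absolute risks changes
nothing) and maps to `1 − c` when case/control labels are swapped.
Bootstrap uncertainty resamples whole matched sets — the exchangeable unit
under this design; the within-set dependence would be broken by
subject-level resampling. Percentile and Wald-on-bootstrap-SE intervals
are both available since the convention is not standardized.

The combined questionnaire + PRS score is leave-one-matched-set-out: set s
is scored with conditional-logistic coefficients fitted on all other sets
(seeded at the full-data optimum, then re-converged), so no subject's
combined score uses her own set's outcome. Under multiple imputation the
LOO procedure runs inside each completed dataset and the resulting
c-indices are pooled by Rubin's rules. The paired AUC difference uses the
same resampled sets for both scores; its p-value is a two-sided normal
approximation on the bootstrap SE.

## Multiple imputation

A deliberately small fully-conditional-specification imputer stands in for
heavyweight survey imputation software: each incomplete categorical
covariate is modelled by (multinomial) logistic regression on the other
covariates plus case status and age, missing cells are drawn from the
fitted predictive distribution, 10 cycles, covariates visited in order of
increasing missingness, M = 10 completions by default. The pooling step —
not the imputation engine — is what the downstream results depend on;
pooling uses `θ̄`, `W̄`, `B`, `T = W̄ + (1+1/M)B` and the classic df
`ν = (M−1)(1 + W̄/((1+1/M)B))²` (no small-sample correction; flagged
option). Each completed dataset re-derives the questionnaire absolute
risk from its (imputed) covariates, so imputation uncertainty propagates
into AUCs and NRI.

## Reclassification and NRI

Two nested logistic models (log absolute risk; log absolute risk + PRS)
are fitted to the case–control data. Adding `log{kρ(age)/(1−ρ(age))}` to
the linear predictor converts sampling odds to population odds: with an
intercept-only model and 1:k sampling the fitted intercept is `log(1/k)`,
and the offset turns it into `logit(ρ)`. ρ is applied per subject through
5-year age bands (the band width is a choice; the incidence table is a
user input, and the packaged default is a synthetic smooth curve with the
shape and scale of published rates for the target population, not a
registry extract). Risks are categorized closed-left at 1.66% and 2.5%
(0.0166 falls in the middle band, 0.025 in the top one). The categorical
NRI is `[P(up|case) − P(down|case)] + [P(down|control) − P(up|control)]`;
its within-imputation variance uses the asymptotic multinomial form
`[p_up + p_down − (p_up − p_down)²]/n` summed over the two groups. Per-
imputation NRIs are averaged and their variance pooled by Rubin's rules
with a normal-approximate CI. The presentation cross-tabulation averages
each woman's predicted risks over imputations *before* categorizing —
this deliberately differs from the mean of per-imputation tables, and a
test exhibits a fixture where the two disagree. The NRI models contain no
age main effect; only the intercept offset is age-specific.

## Numerical conventions and degenerate inputs

Natural logarithms throughout. Empty weight panels, rho outside (0,1),
risks outside (0,1), matched sets without exactly one case, covariates
with no observed values, and zero control-score variance all raise with
diagnostics rather than propagating NaNs. Quantile boundaries use numpy's
linear-interpolation empirical quantiles. PCA signs are arbitrary and
compared up to sign in tests.

## What the tests show — and what they don't

Passing tests establish that each operation matches its independent oracle
(enumeration, closed forms, generic optimizers, statsmodels' conditional
model), that the pipeline recovers generating parameters at study scale,
and that the published reclassification table reproduces its printed NRI
through this code path. They do not establish performance on real
genotype data: the generator has no LD, no genotype imputation error
correlated with structure, no competing mortality, no informative
missingness beyond case status, and its questionnaire model is exactly
log-additive. Real-data odds ratios and AUCs therefore cannot be — and
are not — reproduced here; the synthetic checks verify the *machinery*,
calibrated to the published effect and discrimination scale.

## Problem sizes

Unit tests run at hundreds of sets; study-scale checks use ~2,500 1:2
sets from 35,000 subjects and 300 variants, sizes chosen so the full suite
and the acceptance script each complete in minutes on a single CPU while
keeping Monte-Carlo error well inside the asserted tolerances.
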