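# Methods

## The scientific setting

Gliomas carrying an IDH1-R132H mutation produce the oncometabolite
d-2-hydroxyglutarate (2-HG).  In a perioperative ("window-of-opportunity")
trial, patients with recurrent nonenhancing mIDH1 low-grade glioma are
randomized to an IDH inhibitor — vorasidenib 50 or 10 mg q.d., ivosidenib
500 mg q.d. or 250 mg b.i.d. — or to no treatment for roughly four weeks
before a planned resection.  Tumor 2-HG concentration in the resected tissue
is the primary pharmacodynamic endpoint.  Because pre-treatment biopsies are
not feasible, the untreated comparison pools a handful of randomized
untreated patients with a bank of archival untreated mIDH1 tumors through a
Bayesian dynamic-borrowing design.

This package implements that analysis end to end and couples it to a
synthetic-cohort generator so every stage runs without any external data.

## The borrowing model

Observations are log10 tumor 2-HG.  For group g (four treated arms, plus the
internal and external untreated control sources):

    y_gj | θ_g, σ²_g ~ N(θ_g, σ²_g)
    θ_t ~ N(m₀, v₀)                      treated arms
    θ_c | µ_c, τ² ~ N(µ_c, τ²)          control sources
    µ_c ~ N(m₀, v₀),  τ² ~ IG(a_τ, b_τ),  σ²_g ~ IG(a_σ, b_σ)

The commensurate structure — both control-source means exchangeable around a
control hypermean µ_c with between-source variance τ² — is the minimal
hierarchy that borrows *dynamically*: when the internal and external control
data agree, τ² concentrates near zero and the external bank sharpens µ_c;
when they disagree, τ² grows and the external data are discounted.  This
structure is a reconstruction: published descriptions of such designs state
the ingredients (hierarchical normal model, dynamic borrowing, normal and
inverse-gamma priors, Gibbs sampling) without fixing the hierarchy, so the
package documents its own choice prominently.  Whether borrowing should act
at the observation level instead, or whether the control sources should share
an observation variance, are open alternatives; per-group variances are used
here because the per-arm spreads differ by an order of magnitude.

All full conditionals are conjugate, and the sampler is a hand-written Gibbs
scheme with chains run as a vectorized axis.  Per iteration: each θ_g from a
precision-weighted normal (likelihood precision n_g/σ²_g against the prior —
N(m₀, v₀) for treated arms, N(µ_c, τ²) for control sources); µ_c from the
normal combining the two control-source means; τ² from
IG(a_τ + K/2, b_τ + Σ(θ_c − µ_c)²/2) with K = 2; each σ²_g from
IG(a_σ + n_g/2, b_σ + Σ(y_gj − θ_g)²/2).  Initialization is overdispersed
around data moments with seeded jitter; runs are deterministic given the
seed.

The treatment effect for arm t is the percent reduction relative to the
untreated control level,

    R_t = 100 · (1 − 10^(θ_t − µ_c)),

computed **per retained draw** and then summarized by the posterior mean and
equal-tail credible interval.  Summarizing the transform rather than
transforming the summary matters: R_t is left-skewed, so its posterior mean
sits below the point transform of the posterior means.  Exponents in 10^x
are clamped at 300 (with a warning) to avoid float overflow.

### Priors and the τ² default

Defaults: m₀ = 0, v₀ = 10⁶ (effectively flat on the log10 scale),
σ²_g ~ IG(0.001, 0.001), four chains of 10,000 iterations with 2,000 burn-in.
These are noninformative, and harmless wherever data dominate.

The commensurability variance τ² is the exception and gets a **weakly
informative** default, IG(3, 0.2) (prior mean 0.1 on the squared-log10
scale, i.e. control sources agreeing within roughly a factor of two).  With
only K = 2 control sources, an ε-inverse-gamma prior on τ² leaves a
polynomial posterior tail: τ² occasionally escapes to enormous values, the
conditional s.d. of µ_c (≈ √(τ²/K)) reaches hundreds of log10 units, and
single draws of 10^(θ_t − µ_c) overflow any float — the posterior mean of
R_t is then dominated by these tail excursions and carries no information.
This is the familiar pathology of ε-inverse-gamma priors on hierarchical
variances estimated from very few groups, made catastrophic here by the
exponential transform.  Because borrowing strength is inevitably
prior-sensitive at K = 2, `tau_prior_sensitivity` sweeps (a_τ, b_τ) and
reports how the arm reductions move; all hyperparameters are overridable in
`ModelConfig`.

Wild-type external samples are descriptive only and never enter the model:
the endpoint contrasts treated versus untreated *mIDH1* tumors.

### Diagnostics

Split-chain potential-scale-reduction (Rhat) and effective sample size are
computed per scalar parameter via ArviZ; `summary()` flags any Rhat above
1.01.  Single-chain runs report ESS only, with a warning.

## Synthetic cohorts

The generator's defaults are the study conditions:

* **Arm sizes.**  Presurgery randomization is 12:12:5 (vorasidenib 50 :
  ivosidenib 500 : untreated, the 2:2:1 cohort) plus 10:10 (the 1:1 cohort),
  49 subjects in total.  The default `ArmSpec`s use the evaluable sizes for
  the tissue analyses — 11/7/10/7 treated, 5 internal controls, 61 external
  mIDH1 controls — since those feed the primary analysis.  The evaluable
  per-arm n is configurable because it is not uniquely fixed by the public
  summaries.  The external wild-type bank (descriptive only) defaults to
  n = 20, a typical archival-bank size; its n is never printed anywhere.
* **2-HG.**  Each arm's concentrations are drawn from the base-10 lognormal
  whose *arithmetic* mean and s.d. equal the published per-arm summaries
  (8.9/4.1, 67.5/65.4, 20.9/30.7, 16.8/18.1 treated; 154.9/146.9 internal
  and 276.8/231.4 external controls; 3.7/3.1 wild type, all µg g⁻¹).
  Moment matching: scale² = ln(1 + sd²/mean²)/ln²10,
  location = log10(mean) − (ln10/2)·scale².  The lognormal is the natural
  generative family for a model specified on log10 concentrations; the true
  data-generating link between the published arithmetic summaries and the
  log-scale model is not knowable from the summaries alone.
* **Eligibility flags** are independent Bernoulli with default rates 2/49
  (insufficient tissue), 3/49 (mIDH1 not confirmed), 4/49 (incorrect
  dosing) — the realized exclusion counts of the 49-patient cohort.
* **Biomarkers** (Ki-67 %, 5hmC %, CD3⁺/CD8⁺ densities) are linear in log10
  2-HG with Gaussian noise, truncated at zero rather than redrawn
  (configurable slopes/intercepts/noise).  Ki-67 couples positively, 5hmC
  negatively — the directions the pharmacology predicts.
* **Expression** is a gene × sample matrix, log2-normal background with the
  first `n_signature_genes` linear in the z-scored covariate with
  alternating signs, exponentiated to strict positivity.  It emulates a
  2-HG-associated transcriptional signature, not RNA-seq counts: no
  library-size variation, no overdispersion, no gene–gene correlation.
  Passing recovery tests therefore demonstrates that the rank/enrichment
  machinery works, not that it would rank genes identically in real
  count data.
* **Lesion series**: baseline SPD lognormal (8 ± 4 cm²), visits every 56
  days with multiplicative drift (default −5 %/visit) and lognormal noise;
  20 % of subjects have a complete resection (no residual disease).

## Design operating characteristics

`operating_characteristics` replays the design's simulation-based sizing:
generate a trial under a generative truth, fit the borrowing model, declare
detection when P(θ_t < µ_c | data) > p* (default 0.975 — the detected
*event* is public, the decision rule is this package's definition), repeat.
Reported per cell: detection rate with binomial s.e., mean posterior-mean
reduction, CrI coverage of the true reduction, mean CrI width.  Replicate
seeds are base_seed + index, recorded in the output.  The generative truth
behind the original "approximately 94 % probability of detection" claim was
never published, so the package verifies behavior (type-I-like control at
zero effect, monotone power, near-certain detection under the published
arm summaries) rather than that single number.

The OC default sampler is 2 chains × 3,000 iterations — operating
characteristics average over hundreds of fits, so per-fit Monte-Carlo error
washes out; the calibration tests in the suite use 1,500-iteration fits and
50–200 replicates for the same reason.

## Response evaluation

Best overall response on percent SPD change from the postoperative
baseline: PR ≤ −50 %, minor response in (−50, −25], CR = disappearance of
all lesions, PD ≥ +25 % from the nadir (baseline included, the RANO
convention), SD otherwise.  CR/PR/mR require the next scheduled scan to
sustain at least the same category; an unconfirmed qualifying decrease is
SD.  Subjects resected without residual disease are SD unless new
measurable disease appears.  ORR = CR+PR+mR with a Clopper–Pearson exact
interval from Beta quantiles; percentages round half-up to one decimal.
Clopper–Pearson was adopted because it reproduces all four published ORR
intervals exactly at the printed precision.

## Pharmacodynamic associations

Biomarker–2-HG associations use ordinary least squares with the two-sided
t-test on the slope (n − 2 d.f.); group contrasts use Student's
pooled-variance t-test.  Gene ranking uses

    rank = −log10(unadjusted p) × sign(log2 FC),

with p = 0 clamped to the smallest positive normal double (configurable).
The per-gene association is a *declared simplification*: OLS of log2
expression on the population-z-scored covariate, not a negative-binomial
count model — enough to exercise the ranking and enrichment machinery on
the synthetic matrix.  Multiplicity uses Benjamini–Hochberg step-up.
Preranked enrichment uses the weighted Kolmogorov–Smirnov running sum with
weight |rank|¹, sets restricted to 15–500 genes after intersection, a
seeded gene-sampling null (default 1,000 permutations), NES = ES divided by
the mean |null ES| of matching sign, and a +1-continuity permutation p —
the conventions of fast preranked-GSEA implementations.  The "top split"
comparison z-scores genes, clusters samples by complete linkage on
Euclidean distance, cuts the dendrogram into the two topmost clusters and
contrasts an external variable (log10 2-HG) between them by t-test.

## Numerical and testing notes

* Quantiles are empirical (numpy linear interpolation); equal-tail
  intervals at (1−level)/2 and 1−(1−level)/2.
* The Gibbs sampler is validated three ways: against the conjugate
  closed-form posterior in a collapsed two-group case with (nearly) fixed
  variance; by frequentist CrI coverage of a true 90 % reduction over 200
  simulated trials with the commensurability variance drawn from its
  prior; and by simulation-based calibration (rank uniformity of the true
  treated mean under fully proper, matched priors) at 100 replicates.
* Enrichment scores are checked to 10⁻¹² against a position-by-position
  running-sum oracle; BH against hand-computed vectors and an independent
  implementation; the exact binomial interval against direct inversion of
  binomial tail probabilities for every (x, n ≤ 30).
* Test and acceptance problem sizes (1,500–10,000 Gibbs iterations,
  50–200 replicates, 2,000-gene matrices) were chosen so the full suite
  completes in a few minutes while keeping Monte-Carlo error well inside
  every asserted tolerance.

## Known limitations

* The hierarchy is a documented reconstruction; with two control sources
  the borrowing strength remains prior-sensitive no matter the prior, and
  credible intervals for the percent reduction are accordingly
  prior-dependent (the published intervals are wider than this package's
  defaults produce, consistent with a more diffuse commensurability prior).
* The expression generator does not emulate counts, so differential
  expression realism is out of scope by design.
* RANO-LGG is implemented for SPD series only: non-target lesions,
  steroid use and clinical deterioration — all part of full RANO — are not
  modeled, and progression after a complete response (nadir 0) is not
  flagged.
* Operating characteristics assume the treated-arm truth is lognormal with
  independent subjects; dropout and measurement error are not modeled.
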