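# Methods

This document specifies the statistical models, their assumptions and
parameters, the synthetic-data generators, the numerical choices behind the
implementation, and known limitations.

## 1. Bayesian integration model

### Model

Per-modality old-trial hit counts `y_m` out of `n_m` trials,
`m ∈ {a, v, av}`, are modelled as

```
y_a  ~ Binomial(n_a,  theta_a)
y_v  ~ Binomial(n_v,  theta_v)
y_av ~ Binomial(n_av, theta_av),   theta_av = x_ind * theta_crt
theta_crt = theta_a + theta_v - theta_a * theta_v
```

`theta_crt` is the probability-summation criterion: the probability that at
least one of two *independent* retrieval cues succeeds. The indicator ratio
`x_ind` scales the audio-visual rate relative to that criterion, so `x_ind =
1` encodes exact independence, values below 1 sub-additivity and values
above 1 super-additive integration.

### Priors

- `theta_a, theta_v ~ Beta(5.8, 4.2)` — mildly informative, concentrating
  mass on above-chance, below-ceiling recognition (mean 0.58).
- `x_ind ~ Normal(mu = 1, scale = 0.01)`, truncated implicitly to the
  feasible set (`x_ind > 0` and `theta_av ∈ (0, 1)`).

The **scale of the indicator prior is ambiguous** in the Gibbs-sampling
tradition: BUGS/JAGS-style engines parameterize the normal by its
*precision*, under which 0.01 means SD = 10 — an effectively flat prior that
lets the data place the indicator at the observed ratio of hit rates. Read
as a standard deviation instead, the same number would pin the indicator at
1 and the posterior could never move to ~0.89. The package defaults to the
precision reading (`ModelConfig.ind_scale_meaning = "precision"`); the
standard-deviation reading is selectable. Posterior summaries at realistic
counts are only consistent with the precision reading.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs over `(theta_a, theta_v,
x_ind)`:

- one Gaussian random-walk update per coordinate per iteration;
- proposal scales adapted in batches of 50 toward a 0.44 acceptance rate,
  but **only during a dedicated adaptation phase** (default 1,000
  iterations). Scales are frozen afterwards, so the post-adaptation kernel
  satisfies detailed balance;
- then a discarded burn-in (default 1,000) and retained iterations (default
  10,000 per chain, thinning 1), across 4 chains by default;
- support violations are handled by returning `-inf` from the log posterior
  (automatic rejection), which implements the truncation of the indicator
  prior.

Summaries (means, SDs, HDIs, verdict) default to the **first chain**,
matching the reporting convention of single-chain Gibbs analyses this model
family comes from; `summary_chain="pooled"` uses all chains. Diagnostics
(split R-hat and bulk effective sample size via ArviZ, plus the maximum
lag-1 autocorrelation over chains) always use all chains; a parameter is
flagged when R-hat exceeds 1.01.

The HDI is the shortest contiguous interval containing `ceil(mass * N)`
sorted draws. The verdict compares the 95% HDI of `x_ind` with 1:
entirely below → `sub_additive`, entirely above → `super_additive`,
otherwise `consistent_with_independence`.

### Verification

- **Conjugate oracle**: with the indicator pinned (`fix_x_ind=1`) and data
  in one modality, the model reduces to a Beta-binomial update whose
  posterior is `Beta(5.8 + y, 4.2 + n - y)`; sampled means/SDs match the
  closed form within Monte Carlo error.
- **Grid oracle**: on small counts the posterior means match deterministic
  grid integration of the same density within 0.02.
- **Calibration**: at n = 7,200 per modality, each true parameter falls
  inside its 95% HDI in ≥ 90 of 100 seeded replicates. (The *joint* event —
  all three parameters simultaneously inside their marginal HDIs — has
  probability ≈ 0.95³ ≈ 0.86 for a perfectly calibrated sampler, since the
  three coverage events are nearly independent; calibration is therefore
  asserted per parameter.)

## 2. Signal detection layer

Equal-variance Gaussian model: `d' = z(H) - z(F)`,
`c = -(z(H) + z(F)) / 2`. Hit/false-alarm rates of 0 or 1 make `z`
infinite, so a correction is applied before the transform:

- **log-linear** (default): add 0.5 to each response count and 1 to each
  trial count, *uniformly in every cell* — correcting only boundary cells
  would bias condition contrasts;
- **clamp**: replace 0 by `1/(2N)` and 1 by `1 - 1/(2N)`;
- **none**: raw rates, warning on boundaries.

Within-subject confidence intervals: Cousineau-Morey (per-participant
centring, J/(J-1) bias correction, t-based half-width) by default;
Loftus-Masson (pooled subject-by-condition interaction MS) optionally.

## 3. ANOVA layer

A purpose-built engine for **complete balanced** designs:

- *Repeated measures*: sums of squares from the classical marginal-mean
  (inclusion-exclusion) decomposition; each within effect is tested against
  its own effect-by-subject interaction. No sphericity correction by
  default (the designs of interest have many 2-level factors);
  Greenhouse-Geisser is available behind a flag and matches pingouin's
  epsilon.
- *Mixed*: one equal-sized between-subject factor crossed with within
  factors. The between effect is tested against subjects-within-groups;
  every within-involved effect against its interaction with
  subjects-within-groups.
- Verified against `statsmodels` `AnovaRM` (three within factors, 1e-8
  agreement) and `pingouin.mixed_anova`; `F = t²` holds exactly for
  two-level factors; type-I error is calibrated (≈ 0.05 under null
  simulations).

Effect sizes: partial η² = `F·df1 / (F·df1 + df2)`. Its confidence interval
inverts the noncentral-F distribution (solving `P(F' ≥ F_obs) = (1±level)/2`
for the noncentrality λ) and converts through
`η² = λ / (λ + df1 + df2 + 1)` — the conversion that reproduces published
intervals for these designs; `λ / (λ + N)` is available as
`convention="n"`. A-priori power for a one-df within-subject contrast uses
Cohen's `f² = η²/(1-η²)`, noncentrality `sqrt(f²(n-1))` and the noncentral
t distribution (two-sided); it reproduces the planning value 0.82 for
η² = .28, n = 24, α = .05.

## 4. Designs and generators

### Stock designs

Five study-test congruency designs (`1a`, `1b`, `2`, `3`, `4`), each with
50 movies × 24 clips (8 per length 3.0/3.5/4.0 s), 600 studied targets and
600 foils per participant. Condition cells (study × test modality,
optionally × visual quality) divide targets and foils equally. Every foil
is **yoked** to a target from the same movie, length and condition, and
carries that condition's study label (`condition_study`) so
signal-detection cells partition the trials exactly; for externally loaded
data without that label, foils are shared across the study-modality levels
of their (test modality, length, quality) stratum. Counterbalancing rotates
each clip through all cell × target/foil roles across subgroups of 8
participants (a Latin-square rotation per movie × length block). In the
quality design (`4`), quality is manipulated between movies within
participant, alternating halves across movies.

### Aggregated-count generator

`simulate_counts` draws `y_m ~ Binomial(n, theta_m)` with `theta_av` tied
to the probability-summation criterion through `x_ind`. The default regime
(`DEFAULT_REANALYSIS_RATES`) encodes the pooled two-session recognition
study the integration model reanalyses: 48 participants × 150 old trials
per modality (n = 7,200), unimodal rates 0.55/0.62 (criterion 0.829) and
indicator ratio 0.89 (audio-visual rate ≈ 0.738).

### Trial-level generator

`simulate_experiment` equips each participant with per-condition
sensitivity/criterion values drawn around published condition means
(defaults embed the full condition table of all five experiments:
per-condition d′ and c means and SDs at each clip length). An equal-variance
Gaussian observer answers "old" with probability `Φ(d'/2 - c)` on old items
and `Φ(-d'/2 - c)` on foils (foils use their yoked condition's values).
Sampled d′ values are not truncated at zero.

Published per-condition SDs conflate between-participant level differences
with condition-specific variability, and studies of this kind report large
correlations between repeated measures. The generator therefore splits the
SD into a **shared participant intercept (70% of the variance by default,
`shared_var_frac=0.7`) plus a condition-specific remainder**. This choice
reproduces the reported magnitudes of within-subject t and F statistics at
n = 24; `shared_var_frac=0` gives fully independent per-condition draws.
Observed condition SDs slightly exceed the generative SDs because binomial
measurement noise at 50 old + 50 foil trials per cell adds to the
between-participant variance — expected, and visible in wide panels.

Seeding uses `numpy` `SeedSequence` spawn keys per participant (and per
chain in the sampler), so adding participants or chains never reshuffles
existing ones, and identical seeds give byte-identical pipeline outputs.

## 5. Numerical choices

- Log-domain posterior arithmetic throughout; no likelihood normalisation
  constants (irrelevant for MCMC).
- `scipy.stats` for all distribution functions; `brentq` for the
  noncentral-F inversion (expanding upper bracket, lower bound floored at
  λ = 0).
- ArviZ for split R-hat and bulk ESS; lag-1 autocorrelation computed
  directly.
- HDI by sorted-sample window search, O(N log N).
- ANOVA sums of squares via vectorised marginal-mean inclusion-exclusion on
  a dense balanced array (duplicates and missing cells rejected up front).

## 6. Scope and limitations

- The ANOVA engine requires *complete balanced* data (aggregate or impute
  first) and supports at most one between-subject factor; sphericity
  corrections beyond Greenhouse-Geisser (e.g. Huynh-Feldt) are not
  implemented.
- The integration model assumes pooled counts (no participant-level
  hierarchy) and exchangeable trials within modality; overdispersion from
  participant heterogeneity is not modelled and will tighten HDIs relative
  to a hierarchical treatment.
- The equal-variance observer ignores unequal old/new variance and response
  sureness; the generator draws condition values independently of the
  counterbalancing subgroup.
- The trial-level generator's defaults describe the published *population*
  means; single simulated samples at n = 24 vary as real samples do (the
  congruency pattern is asserted over a seed panel, not per seed).
- `summary_chain="first"` intentionally reproduces a single-chain reporting
  convention; pooled summaries are statistically more efficient and
  available via configuration.
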