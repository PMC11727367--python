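# Methods

This note documents the statistical model behind `emomem`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Scoring model

### Signal-detection indices

Item memory is scored as d′ = z(hit rate) − z(false-alarm rate) on
harmonized old/new judgments (Remember, Know, and Old responses all count as
"old" calls). For Remember/Know tasks, recollection and familiarity are
separated under the **independence assumption**: recollection d′ uses
Remember-restricted hit and false-alarm rates, and familiarity d′ rescales
the Know rates by the opportunity for a familiarity response,
K/(1 − R), on both the hit and the false-alarm side. The assumption is that
familiarity operates on the trials recollection did not claim; under the
generative model below this inversion is exact.

All rates pass through the **1/(2N) extreme-rate correction** (0 → 1/(2N),
N → 1 − 1/(2N)) before the normal quantile. This is the standard
signal-detection practice for keeping indices finite at ceiling/floor; any
other correction (log-linear, +0.5) would change values only in extreme
cells. If the conditional familiarity ratio still lands outside (0, 1) —
possible when K ≥ 1 − R — the cell is undefined and reported missing.

### Unbiased hit rate

Source memory is scored with Hu = stimulus accuracy × response precision:
`hits/(hits+incorrect) · hits/times_chosen`, computed per participant ×
true category, overall and conditionally within Remember and Know judgment
strata. Two conventions matter and are fixed here:

- **`times_chosen` counts attributions among recognized old items only**,
  within the judgment stratum; attributions attached to false-alarmed new
  items are excluded everywhere. The alternative (including FA attributions
  in the denominator) would deflate precision for participants with liberal
  response criteria; the chosen reading keeps Hu a pure old-item measure.
- **Zero hits with positive denominators give Hu = 0; a zero denominator
  gives a missing cell.** Missing cells are dropped row-wise by the models,
  which is why pooled analyses report fewer observations than
  participants × cells.

A consequence of the shared `times_chosen` denominator worth knowing: the
categories are *coupled*. Improving source accuracy for emotional categories
reduces misattributions that would otherwise land in the neutral column, so
neutral Hu rises slightly too. Similarly, raising recollection rates for all
categories at once leaves the expected Remember-stratum Hu at ρ² (accuracy
and precision both equal ρ under symmetry); only asymmetric changes move it.
The property tests probe the per-category (asymmetric) monotonicity.

## Mixed models

Indices are modeled with Gaussian linear mixed models fitted by **full
maximum likelihood** (never REML, so likelihood-ratio tests across fixed
structures are valid). Random effects are intercepts for participant and for
study-group (study × group; 11 levels in the full design). Participants are
strictly nested within study-groups, so the crossed specification is fitted
as a two-level nested model (study-group as the outer grouping, participant
as a variance component within it) — algebraically identical and much
faster. When study-group has a single level it degenerates to
participant-only intercepts. Fixed factors use treatment coding with
reference levels neutral / know / free_viewing / control / remember_know /
EEG; `n_new_items` enters as a continuous covariate.

**Parsimonious selection** is forward stepwise under a fixed, documented
candidate order (encoding_instruction, retrieval_task, environment, group,
n_new_items; then memory_type for the judgment-split analyses; then pairwise
interactions among retained terms, then any explicitly offered higher-order
terms whose constituents were all retained). A term is kept iff the χ²
likelihood-ratio test against the current model has p < 0.05 on identical
rows. Affective category is always in the model and never tested for
removal. Terms that are unidentifiable in a given dataset (single observed
level, or aliased with retained terms — rank-deficient design) are recorded
in the selection trace as untestable and skipped rather than crashing the
search.

**Post-hoc contrasts** compare estimated marginal means: model predictions
per cell of the requested factor grid, averaged with *equal weights* over
the levels of the other fixed factors (continuous covariates at their mean).
All pairwise differences within the grid form the Tukey family; p-values
come from the studentized-range distribution. Denominator degrees of freedom
use the residual approximation n_obs − n_fixed. A Satterthwaite or
Kenward-Roger approximation would shrink df for between-participant
contrasts, but df enters only the p-value tail, the t statistics themselves
are df-free, and the residual df is deterministic and dependency-light;
t-values are the quantity to compare across implementations.

**Bayes factors** use the BIC approximation BF₁₀ = exp((BIC₀ − BIC₁)/2)
between the final model and the same model with the effect of interest
removed, on identical rows. This corresponds to a unit-information prior; it
is deterministic and reciprocal by construction, but typically more
conservative toward H₁ than default mixture-of-g priors, so BF magnitudes
should be read as order-of-magnitude evidence, not calibrated posterior
odds. Evidence labels use graded bins on the H₀ side (0.3–1 anecdotal,
0.1–0.3 moderate, 0.03–0.1 strong, 0.01–0.03 very strong, < 0.01 decisive)
with the H₁ side defined as their exact reciprocals (boundaries 10/3, 10,
100/3, 100), which keeps `classify(x)` and `classify(1/x)` mirror-symmetric
and the bins exhaustive. BF₁₀ = 1 is "none".

## Synthetic-data generator

One old item of category c is **recollected** with probability r_c (a
high-threshold process); recollected items yield "remember" and a correct
source attribution with probability ρ_rec,c, otherwise a wrong category
drawn from the attribution-bias weights. Non-recollected items draw a
familiarity strength x ~ N(f_c, 1) against a criterion k: above → "know"
(correct source with probability ρ_fam,c), below → "new". New items yield a
false "remember" with probability ε, otherwise x ~ N(0, 1) against the same
criterion. Old/New blocks collapse remember/know into "old". Participant and
study-group random intercepts (SDs σ_participant, σ_studygroup) and group
shifts (e.g., the stress increment to emotional-category ρ_rec) act
additively on the probit scale of r and on f.

This family was chosen because it is the **minimal model under which the
independence scoring is well-specified**: expected recollection d′ is
z(r_c) − z(ε) and expected familiarity d′ is exactly f_c, so
`expected_indices` provides closed-form oracles for every index (expected Hu
is computed from expected counts — the large-sample limit of the simulated
index). False "remember" responses to new items enter through a single ε
rather than a second criterion on the strength axis, keeping recollection a
threshold process and the familiarity oracle closed-form.

Default parameters live in `configs/default_simulation.yaml`, not in code:
r = 0.35 and f = 0.8 for every category (no item-memory category effect),
ρ_rec = 0.55 neutral vs 0.70 emotional, ρ_fam = 0.40 everywhere, ε = 0.02,
k = 1.0, uniform bias, σ_participant = 0.35, σ_studygroup = 0.15 (probit
scale), and a +0.25 probit stress shift to emotional ρ_rec. These magnitudes
are plausibility choices producing realistic behavior — overall hit rates
near 0.6, false-alarm rates near 0.17, item d′ near 1.2, overall Hu near
0.3 — and a recollection-driven emotional source-memory advantage; they are
not estimates from any dataset. The design layout (`table1_design`) encodes
the pooled seven-study structure: 11 study-group blocks, N = 333, studies 1
and 4 with Old/New retrieval (study 4 with only unpleasant/neutral
contexts), one free-viewing study, EEG/MRI/eye-tracker environments, and
control/stress/stress-delay groups. Rescaled designs reallocate block sizes
proportionally with largest-remainder rounding (minimum 2 per block).

**What passing tests do and do not show.** The generator produces Gaussian
random intercepts, binomial trial noise, and exactly the factor structure
the models assume — no response-criterion drift, no item-level random
effects, no serial-position or fatigue effects, no demographic covariates,
and no encoding-phase (imagination-success) responses. Calibration results
(type-I error ≈ 0.05, >95% sign recovery of the recollection × emotion
interaction at 120 participants) therefore certify the *pipeline's*
correctness under its own assumptions, not the robustness of the design to
real-data violations of them.

## Problem sizes and numerical choices

- Calibration experiments run at reduced but statistically meaningful
  scales, chosen as the smallest designs at which the tested property is
  expressed: type-I calibration uses 500 replicates of 30 participants × 3
  categories × 30 old/90 new items; interaction recovery uses 200 replicates
  of the pooled design rescaled to 120 participants; generator-oracle
  agreement uses 50,000 trials per cell.
- LRT χ² is clipped at 0 (boundary noise can make the larger model's ML
  log-likelihood infinitesimally smaller); df is the fixed-coefficient count
  difference.
- Coefficient p-values and CIs use the normal (Wald) approximation
  (CI = b ± 1.96·SE), standard for ML mixed models at these sample sizes.
- Singular random-effect structures are reported by the fitter as near-zero
  variance with a convergence warning, not an error; rank-deficient fixed
  designs raise a model error naming the formula.
- Ties and determinism: all simulation randomness flows from a single
  `numpy` Generator seeded per run; replicate seeds are spawned from the
  root seed, so every experiment is exactly reproducible.

## Known limitations

- The BIC Bayes factor is an approximation; bridge-sampling or
  mixture-of-g-prior BFs can differ by an order of magnitude for small
  effects. The interface accepts alternative methods behind the same
  contract.
- Residual-df Tukey p-values are slightly anti-conservative for
  between-participant contrasts relative to Satterthwaite df.
- `expected_indices` is population-level only (zero random-intercept SDs);
  with participant heterogeneity, nonlinear z-transforms make the mean of
  per-participant indices differ from the index of mean rates.
- The reader supports the documented CSV dialect only; per-study and pooled
  files are both accepted since they differ only by row concatenation.
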