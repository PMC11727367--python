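# emomem

Pooled (individual-participant-data) analysis of emotion effects on episodic
**item** and **source** memory, for recognition experiments in which neutral
objects are encoded against pleasant, neutral, or unpleasant background
scenes and retrieval is probed about a week later with Old/New or
Remember/Know judgments plus a source-category question.

The package is aimed at memory researchers who want to score trial-level
Remember/Know data into signal-detection and unbiased-hit-rate indices, fit
linear mixed models across pooled multi-study designs, and calibrate the
whole chain against a generative model with known ground truth.

## What it computes

**Item memory** is indexed by sensitivity

> d′ = z(P(Old)) − z(P(False Alarm)),

with Remember/Know responses collapsed to "old" calls. For Remember/Know
tasks the two retrieval processes are separated under the independence
assumption:

> d′_recollection = z(P(Remember hit)) − z(P(Remember FA)),
> d′_familiarity  = z(K_hit / (1 − R_hit)) − z(K_FA / (1 − R_FA)).

Extreme rates are corrected by the 1/(2N) rule before the normal quantile,
so every index is finite.

**Source (contextual) memory** is indexed by the unbiased hit rate

> Hu = Hit/(Hit + Incorrect) × Hit/(N° times the category was chosen),

the conjoint probability of identifying an item's source category correctly
(stimulus accuracy) and of that response category being correct when used
(response precision). Conditional Hu restricts the counts to items
recognized under one memory judgment (Remember or Know). Cells with a zero
denominator are missing, never zero.

**Inference** uses Gaussian linear mixed models fitted by full maximum
likelihood, with random intercepts for participant and study-group (the
study × group combination). Methodological factors (encoding instruction,
retrieval task, environment, stress group, number of new items) enter by
parsimonious forward selection: a term is kept only if the χ² likelihood
ratio against the reduced model is significant; interactions are offered
only among retained terms; affective category is never dropped. Significant
effects are followed up with Tukey-HSD contrasts on estimated marginal
means, and each retained effect gets a BIC-approximation Bayes factor
(BF₁₀ = exp(ΔBIC/2)) with a graded evidence label.

**Synthetic data** come from a dual-process generative model —
high-threshold recollection plus equal-variance signal-detection
familiarity — over the pooled seven-study design (11 study-group blocks,
N = 333, 2–3 affective categories, 44–60 old items per category, 66–180 new
items, Old/New vs Remember/Know tasks, control/stress/stress-delay groups).
Under this model the Remember/Know independence scoring is exactly
well-specified (expected familiarity d′ equals the generative familiarity
sensitivity), so the generator doubles as a closed-form oracle for the whole
pipeline.

## Worked example

Simulate the pooled design scaled to 120 participants, score it, and test
the memory-type × affective-category interaction on source memory:

```python
from emomem import (ModelSpec, SimulationConfig, build_index_table, fit_lmm,
                    lr_test, simulate_trials, table1_design)
from emomem.bayes_eval import bic_bayes_factor
from emomem.synthetic_data import default_config

cfg = SimulationConfig(design=table1_design(120),
                       truth=default_config().truth, seed=42)
trials, truth = simulate_trials(cfg)
table = build_index_table(trials)

mem = table[table["memory_type"].isin(("remember", "know"))]
additive = fit_lmm(mem, ModelSpec("hu", ("affective_category", "memory_type")))
interaction = fit_lmm(mem, ModelSpec(
    "hu", ("affective_category", "memory_type",
           "affective_category:memory_type")))
lrt = lr_test(additive, interaction)
bf = bic_bayes_factor(interaction, additive)
```

Output (`interaction.coef_table().round(3)` plus the test):

```
                                                              b     SE  CI_low  CI_high       t      p
Intercept                                                 0.158  0.011   0.136    0.181  13.787  0.000
affective_category[T.pleasant]                            0.002  0.015  -0.028    0.032   0.151  0.880
affective_category[T.unpleasant]                          0.006  0.015  -0.024    0.036   0.418  0.676
memory_type[T.remember]                                   0.217  0.015   0.187    0.247  14.217  0.000
affective_category[T.pleasant]:memory_type[T.remember]    0.093  0.022   0.051    0.136   4.318  0.000
affective_category[T.unpleasant]:memory_type[T.remember]  0.125  0.022   0.083    0.167   5.797  0.000
LRT: chi2(2) = 34.89, p = 2.65e-08
BF10 = 7.05e+04 (decisive H1)
```

Read: within Know (familiarity) judgments, source memory is flat across
affective categories (the two `affective_category[...]` rows are ≈ 0); the
Remember-judgment advantage for emotional contexts appears as the positive
interaction coefficients — exactly the recollection-driven source-memory
pattern the generator's ground truth encodes (higher source accuracy given
recollection for pleasant/unpleasant contexts).

The same chain is available from a shell:

```sh
emomem simulate --seed 42 --out trials.csv
emomem score --trials trials.csv --out index.csv
emomem fit --index index.csv --response hu --analysis-set by_memory_type --out fit.json
```

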