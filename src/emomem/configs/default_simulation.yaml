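# Default generative parameters for the pooled seven-study design.
#
# The ground truth qualitatively mirrors a recollection-driven source-memory
# advantage for emotional (pleasant/unpleasant) contexts, amplified by
# pre-encoding stress, with no item-memory effect of affective category:
# r (recollection probability) and f (familiarity sensitivity) are equal
# across categories, while rho_rec (source accuracy given recollection) is
# higher for emotional categories and receives a further probit-scale stress
# increment.  Attribution bias is uniform.
seed: 0
design: table1          # the 11 study-group blocks, N = 333
truth:
  epsilon: 0.02         # false-"remember" probability for new items
  criterion_know: 1.0   # strength criterion for a "know" response
  sigma_participant: 0.35   # participant random intercept SD, probit scale
  sigma_studygroup: 0.15    # study-group random intercept SD, probit scale
  bias:
    pleasant: 1.0
    neutral: 1.0
    unpleasant: 1.0
  categories:
    neutral:    {r: 0.35, f: 0.8, rho_rec: 0.55, rho_fam: 0.40}
    pleasant:   {r: 0.35, f: 0.8, rho_rec: 0.70, rho_fam: 0.40}
    unpleasant: {r: 0.35, f: 0.8, rho_rec: 0.70, rho_fam: 0.40}
  group_effects:
    stress:
      rho_rec_shift: {pleasant: 0.25, unpleasant: 0.25}
    stress_delay: {}
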