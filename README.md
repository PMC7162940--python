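# audlearn

Analysis pipeline for auditory category-learning experiments: latent
performance-state modelling, task-design effect screening, and early
classification of learners versus non-learners — together with a
design-faithful synthetic cohort generator, so the whole chain is testable
without access to restricted behavioural data.

## The problem

In a rule-based auditory category-learning task, participants hear
frequency-modulated tones varying in five dichotomous features (duration,
pitch direction, loudness, frequency band, modulation speed — 160 distinct
tones) and must discover, from trial-by-trial feedback over 240 trials,
which *duration × direction* combination defines the target category. Each
participant is assigned one of four target configurations and one response
button; 25% of trials are targets. At the end, a questionnaire determines
whether they learned the rule (label L) or not (notL).

Three questions drive the analysis:

1. **How do participants evolve toward learning?** Performance per 10-trial
   block is summarised as *block sensitivity* (hit rate) and *block
   specificity* (correct-rejection rate). Pooled block values are modelled
   as a K-component 1-D Gaussian mixture fitted by EM, with K chosen via
   `BIC = ln(n)·3K − 2 ln Λ̂`; each block is assigned to its
   maximum-posterior component, giving a per-participant sequence of
   high / med / low performance states. Mann-Whitney U tests then screen
   for response-button and configuration effects on the number of
   high-performance blocks (overall and within the first / middle / last
   8 blocks), with a two-band significance scheme (p < 0.05 significant,
   p < 0.2 marginal) and no multiple-comparison correction.
2. **How does performance saturate?** Cumulative sensitivity/specificity at
   trial *i* uses the strict prefix of trials 1..i−1, averaged per
   configuration × button group.
3. **How early are L and notL separable?** Per-participant features —
   block sensitivity and specificity over six 40-trial blocks plus the two
   design factors — feed a gradient-boosted tree classifier over nested
   feature subspaces (`upto_40` … `upto_200`, `complete`), evaluated by
   stratified 5-fold cross-validated balanced accuracy
   `(TPR + TNR)/2`, with L instances weighted `#notL/#L` and notL weighted 1.

Because the original participant data are available only on request, the
`cohort` module simulates experiment-faithful cohorts: the published
allocation of 76 participants over 4 configurations × 2 buttons (62 L /
14 notL), pseudo-randomised schedules with exact block balance, and a
per-block 3-state Markov chain with Bernoulli emissions whose per-state
response probabilities default to the published state means.

## Worked example

```python
from audlearn.cohort import generate_cohort, cohort_to_frame
from audlearn.metrics import block_series_frame
from audlearn.states import fit_gmm_em, state_labels
from audlearn.dynamics import high_block_counts, button_effect_test
from audlearn.classify import build_feature_table, stratified_cv

records = generate_cohort(master_seed=7)          # 76 participants
frame = cohort_to_frame(records)
blocks = block_series_frame(frame, "sensitivity", 10)   # 1824 block values
model = fit_gmm_em(blocks["value"].to_numpy(), 3, seed=7)
print(model.means.round(4))                       # [0.     0.5229 1.    ]

blocks["state"] = state_labels(model, blocks["value"].to_numpy())
meta = frame.drop_duplicates("participant_id")[
    ["participant_id", "config", "button", "label"]]
counts = high_block_counts(blocks, meta)
res = button_effect_test(counts)
print(f"U={res.U}, p={res.p:.3f}")                # U=822.5, p=0.274

table = build_feature_table(frame)
for name in ("upto_40", "upto_200", "complete"):
    rep = stratified_cv(table, name, seed=7)
    print(name, f"{rep.mean:.3f} (+/- {rep.ci_half_width:.3f})")
# upto_40  0.571 (+/- 0.157)
# upto_200 0.933 (+/- 0.185)
# complete 0.933 (+/- 0.185)
```

The fitted mixture puts one near-point state at block sensitivity 1.0
(the "high" state, ~71% of blocks in this simulated cohort), a broad
mid-performance state near 0.52, and a near-point low state at 0; the
U test compares left- vs right-button high-block counts (here not
significant for this seed — the planted left-button advantage is modest);
and cross-validated balanced accuracy climbs from 0.57 using only the
first 40 trials to 0.93 at 200 trials, i.e. in this simulated cohort the
last block adds nothing to class separation.

The same pipeline runs end to end from the shell:

```bash
audlearn run --seed 7 --out-dir runs/demo    # writes manifest + all stages
audlearn simulate --seed 7 --out cohort.csv  # or stage by stage
```

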