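"""Classify ICPP vs normal trials with tuned classical models.

Feature matrices are split 8:2 by subject (both trials of a subject stay on
one side), five classifier families are tuned by 10-fold grid-search
cross-validation on the training split, and the held-out test set is scored
with the study's metrics: accuracy, weighted precision/recall/F1, and
specificity for the normal class, all in percent.
"""

import numpy as np

from nirsicpp import (FeatureExtractor, NoiseConfig, SplitSpec, evaluate,
                      run_preprocess, sample_cohort, segment_trials,
                      split_dataset, tune_and_train)

cohort = sample_cohort(
    {("normal", "female"): 14, ("normal", "male"): 6,
     ("ICPP", "female"): 14, ("ICPP", "male"): 6},
    noise=NoiseConfig(white_sd=0.08), seed=9,
)
segments = []
for rec in cohort:
    segments.extend(segment_trials(run_preprocess(rec), rec.paradigm))
y = np.array([s.label for s in segments])
sids = np.array([s.subject_id for s in segments])

tr, te = split_dataset(np.zeros((len(y), 1)), y, SplitSpec(seed=1), subject_ids=sids)
train_segs = [segments[i] for i in tr]
test_segs = [segments[i] for i in te]
print(f"{len(tr)} training / {len(te)} test trials (subject-level split)")

fx = FeatureExtractor("A").fit(train_segs)
Ftr, Fte = fx.transform(train_segs), fx.transform(test_segs)

for family in ("discriminant", "tree", "nearest-neighbor"):
    model, best, cv_acc = tune_and_train(Ftr.values, Ftr.labels, family, seed=1)
    rep = evaluate(model, Fte.values, Fte.labels, model_id=family, feature_set="A")
    print(f"{family:17s} CV acc {100 * cv_acc:5.1f}% | test acc {rep.accuracy:5.1f}% "
          f"prec {rep.precision_weighted:5.1f}% rec {rep.recall_weighted:5.1f}% "
          f"F1 {rep.f1_weighted:5.1f}% spec {rep.specificity:5.1f}%")
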