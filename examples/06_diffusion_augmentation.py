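"""Augment HbO training trials with a conditional diffusion model.

A denoiser conditioned on the timestep, class label and per-trial GLM
beta-vector is trained on real training segments only (linear noise
schedule 0.001-0.02 over 200 steps, MSE loss, AdamW). Ancestral sampling
then generates synthetic segments matching the training class proportions,
doubling the training set while the test set stays entirely real.
"""

import numpy as np

from nirsicpp import (NoiseConfig, TrainConfig, augment_train_set,
                      run_preprocess, sample_cohort, sample_cddpm,
                      segment_trials, train_cddpm)

cohort = sample_cohort(
    {("normal", "female"): 10, ("ICPP", "female"): 10},
    noise=NoiseConfig(white_sd=0.08), seed=21,
)
segments = []
for rec in cohort:
    segments.extend(segment_trials(run_preprocess(rec), rec.paradigm))
train, test = segments[:32], segments[32:]

state = train_cddpm(train, TrainConfig.desk_scale(), seed=0)
print(f"trained {len(state.training_log)} epochs; "
      f"loss {state.training_log[0]:.3f} -> {state.training_log[-1]:.3f}")

for label, name in ((0, "normal"), (1, "ICPP")):
    synth = sample_cddpm(state, 8, label, seed=100 + label)
    real = np.stack([s.data for s in train if s.label == label])
    print(f"{name}: synthetic mean {synth.mean():+.3f} vs real mean {real.mean():+.3f} umol/l")

augmented = augment_train_set(train, state, test_segments=test, seed=1)
n_synth = sum(s.synthetic for s in augmented)
print(f"augmented training set: {len(augmented)} trials "
      f"({len(train)} real + {n_synth} synthetic); test set untouched ({len(test)} real)")
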