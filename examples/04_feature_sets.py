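"""Build the five hemoglobin feature sets from preprocessed trials.

A: time-domain stats of the most negatively correlated channel pair (8);
B: first 3 PCs of every channel (30); C: A plus the pair channels' PCs (14);
D: PC1 of each of the first 3 EMD intrinsic mode functions per channel (30);
E: per-channel GLM task beta from each trial's own window (10).
"""

from nirsicpp import (FeatureExtractor, NoiseConfig, run_preprocess,
                      sample_cohort, segment_trials)

cohort = sample_cohort(
    {("normal", "female"): 8, ("ICPP", "female"): 8},
    noise=NoiseConfig(white_sd=0.08), seed=5,
)
segments = []
for rec in cohort:
    segments.extend(segment_trials(run_preprocess(rec), rec.paradigm, species="HbO"))
print(f"{len(segments)} trials of shape {segments[0].data.shape} (channel x second)")

for set_id in "ABCDE":
    fx = FeatureExtractor(set_id).fit(segments)
    fm = fx.transform(segments)
    extra = ""
    if fx.pair is not None:
        extra = (f"  [pair ch{fx.pair.i + 1}-ch{fx.pair.j + 1}, "
                 f"picked in {fx.pair.selection_frequency:.0%} of trials, "
                 f"mean r {fx.pair.mean_correlation:.2f}]")
    print(f"Feature {set_id}: {fm.values.shape[1]} columns, "
          f"e.g. {list(fm.columns[:2])}{extra}")
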