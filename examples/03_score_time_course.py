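"""Score an EMT time course with a trained model.

Trains on a synthetic plate, then scores its aggregated profiles: Isolation
Forest outlier removal per condition, class probabilities from the model,
the weighted EMT score per field, per-well summaries with 95% CIs, and a
one-way ANOVA with Tukey pairs across conditions.
"""

import tempfile

import numpy as np

from orgemt import PipelineConfig, SyntheticPlateConfig, run_score, \
    run_train, simulate_plate

plate = SyntheticPlateConfig(
    cells_per_field=60, n_informative=12, n_redundant=12, n_noise=40,
    seed=11)  # full 10 wells x 9 fields design, reduced feature count
cells = simulate_plate(plate)
cfg = PipelineConfig(random_seed=11)
with tempfile.TemporaryDirectory() as td:
    trained = run_train(cells, td, cfg, class_order=list(plate.conditions))
    scored = run_score(trained.model, trained.profiles, config=cfg)

means = scored.scores.groupby("condition", observed=True)[
    "emt_score"].mean().reindex(list(plate.conditions))
print("mean EMT score per condition (weights: Control=1 ... 8d=6.07):")
print(means.round(2).to_string())
print(f"\noutlier fields removed: {len(scored.flagged)}")
print(f"one-way ANOVA: F = {scored.comparison.f_statistic:.1f}, "
      f"p = {scored.comparison.p_value:.2e}")
print("\nTukey-adjusted pairwise p-values (first rows):")
print(scored.comparison.tukey.head(4).round(4).to_string(index=False))
print("\nScores rising monotonically from ~1 toward ~6 reproduce the "
      "progressive EMT induction the weighting encodes; the ANOVA confirms "
      "the conditions differ.")
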