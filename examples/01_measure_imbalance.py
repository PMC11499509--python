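"""Quantify multi-label imbalance on a small synthetic cohort.

Draws a frailty-like dataset, prints the per-label imbalance ratios and
the summary measures. IRLbl is 1 for the most frequent outcome and grows
for rarer ones; MeanIR > 1.5 together with CVIR > 0.2 flags the dataset
as imbalanced, which is the condition the resampler targets.
"""

from mltlsmote import imbalance_profile, label_stats
from mltlsmote.synthetic import frailty_like_preset, generate_mld

mld = generate_mld(frailty_like_preset(3000, seed=5))
stats = label_stats(mld)
profile = imbalance_profile(mld)

print(f"{'label':<30}{'count':>7}{'IRLbl':>9}")
for name, count, ratio in zip(mld.label_names, stats.per_label_counts,
                              profile.irlbl):
    print(f"{name:<30}{count:>7}{ratio:>9.3f}")
print(f"\nCard {stats.cardinality:.3f} (mean active labels/instance), "
      f"Dens {stats.density:.3f}, DC {stats.distinct_combinations}")
print(f"MeanIR {profile.mean_ir:.3f}  MaxIR {profile.max_ir:.3f}  "
      f"CVIR {profile.cvir:.3f}  -> imbalanced: {profile.is_imbalanced}")
print(f"minority labels: {[mld.label_names[j] for j in profile.minority_labels]}")
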