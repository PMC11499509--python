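"""Balance an imbalanced multi-label dataset with the hybrid resampler.

Runs per-minority-label SMOTE followed by per-majority-label Tomek-link
cleaning and prints the before/after imbalance profiles. A successful run
moves MeanIR below 1.5 and CVIR below 0.2 — out of the imbalanced region —
by adding synthetic minority instances and pruning borderline majority
ones.
"""

from mltlsmote import ml_tlsmote
from mltlsmote.synthetic import frailty_like_preset, generate_mld

mld = generate_mld(frailty_like_preset(5000, seed=2))
balanced, report = ml_tlsmote(mld, k=5, seed=2)

print(f"instances: {mld.n_instances} -> {balanced.n_instances}")
print(f"{'label':<30}{'added':>7}{'removed':>9}{'IRLbl before':>14}"
      f"{'IRLbl after':>13}")
for j, name in enumerate(mld.label_names):
    print(f"{name:<30}{report.synthetic_added[j]:>7}"
          f"{report.removed_by_tomek[j]:>9}"
          f"{report.before.irlbl[j]:>14.3f}{report.after.irlbl[j]:>13.3f}")
print(f"\nMeanIR {report.before.mean_ir:.3f} -> {report.after.mean_ir:.3f}  "
      f"(balanced region: <= 1.5)")
print(f"CVIR   {report.before.cvir:.3f} -> {report.after.cvir:.3f}  "
      f"(balanced region: <= 0.2)")
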