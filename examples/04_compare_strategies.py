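"""Fit the six multi-label strategies and compare them on one dataset.

Runs the resampled-train / untouched-test protocol with threefold CV on a
small frailty-like draw, then prints the five evaluation measures per
strategy for both routes. AUROC/AP/F1 are scores (1 best); HL/RL are
losses (0 best). The `cv` block is computed on the balanced (resampled)
training data, the `test` block on untouched imbalanced data — the two can
disagree, and the methods note explains why.
"""

from mltlsmote import run_experiment
from mltlsmote.synthetic import frailty_like_preset, generate_mld

mld = generate_mld(frailty_like_preset(1200, seed=4))
report = run_experiment(
    mld, resampler="tlsmote",
    strategies=("br", "cc", "lp", "rakel", "clr", "mlknn"),
    folds=3, seed=4)

print(f"train {report['config']['n_train']} -> resampled "
      f"{report['config']['n_train_resampled']}; "
      f"test {report['config']['n_test']} (untouched)")
for split in ("cv", "test"):
    print(f"\n[{split}]" + "".join(
        f"{m.upper():>8}" for m in ("auroc", "ap", "f1", "hl", "rl")))
    for strategy, row in report[split].items():
        print(f"{strategy:<6}" + "".join(
            f"{row[m]:>8.3f}" for m in ("auroc", "ap", "f1", "hl", "rl")))
    std = report[f"{split}_std"]
    print("std   " + "".join(
        f"{std[m]:>8.3f}" for m in ("auroc", "ap", "f1", "hl", "rl")))
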