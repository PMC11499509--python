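"""Aggregate model performance across datasets by average rank.

Given a models x datasets table of a metric (here: average precision of
six strategies on four differently-resampled datasets), each column is
ranked (rank 1 = best, ties share the average rank) and ranks are averaged
across columns. Lower average rank = more consistently strong model.
"""

import pandas as pd

from mltlsmote import average_rank

ap = pd.DataFrame(
    {
        "base": [0.62, 0.51, 0.43, 0.57, 0.55, 0.64],
        "undersampled": [0.58, 0.65, 0.50, 0.50, 0.53, 0.62],
        "oversampled": [0.73, 0.64, 0.70, 0.67, 0.75, 0.70],
        "hybrid": [0.79, 0.62, 0.79, 0.75, 0.83, 0.72],
    },
    index=["BR", "CC", "LP", "RAkEL", "CLR", "MLkNN"],
)

print("average precision table:")
print(ap)
print("\naverage rank (1 = best):")
print(average_rank(ap).round(2).sort_values())
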