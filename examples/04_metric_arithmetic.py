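"""Metric arithmetic: confusion counts -> precision/recall/F1/mIoU, and the
label-count-weighted F1 average used for cross-model comparison.
"""

import numpy as np

from dcdnet import (confusion_counts, f1_from_pr, miou, precision_recall_f1,
                    weighted_average)

# a toy prediction/ground-truth pair
rng = np.random.default_rng(3)
gt = (rng.random((64, 64)) > 0.8).astype(int)
pred = np.clip(gt + rng.normal(0, 0.4, gt.shape), 0, 1)

c = confusion_counts(pred, gt, threshold=0.5)
p, r, f1 = precision_recall_f1(c)
print(f"counts: TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}")
print(f"precision={p:.2f}%  recall={r:.2f}%  F1={f1:.2f}%  "
      f"mIoU={miou(pred, gt):.2f}%")

# F1 is the harmonic mean of precision and recall:
print(f"\nf1_from_pr(76.02, 71.04) = {f1_from_pr(76.02, 71.04)}  "
      "(harmonic mean of a per-type precision/recall pair)")

# weighted average across caries types, weighted by lesion-label counts
per_type_f1 = (73.45, 66.15, 11.21)
label_counts = (746, 1627, 378)
wavg = weighted_average(per_type_f1, label_counts)
print(f"weighted_average({per_type_f1}, weights={label_counts}) = {wavg:.2f}")
print("-> rare-but-hard Type III drags the weighted score down far less than")
print("   an unweighted mean would suggest; weights are always reported.")
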