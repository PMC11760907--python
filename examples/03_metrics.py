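"""The metric suite on a hand-checkable example.

Four pixels, threshold 0.5: predictions [0.9, 0.2, 0.8, 0.6] against truth
[1, 0, 0, 1] give TP=2, TN=1, FP=1, FN=0.
"""

import numpy as np

from vesselseg.metrics import bce, confusion, ratio_metrics, roc_auc

pred = np.array([0.9, 0.2, 0.8, 0.6])
truth = np.array([1, 0, 0, 1])

c = confusion(pred, truth, threshold=0.5)
print(f"TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}")

r = ratio_metrics(c)
print(f"ACC={r['acc']:.4f} SN={r['sn']:.4f} SP={r['sp']:.4f} "
      f"precision={r['precision']:.4f} F1={r['f1']:.4f}")
print(f"BCE={bce(pred, truth):.4f}  (ln 2 = {np.log(2):.4f} would be a "
      "coin-flip predictor)")
print(f"AUC={roc_auc(pred, truth):.4f}  (probability a random vessel pixel "
      "outscores a random background pixel)")
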