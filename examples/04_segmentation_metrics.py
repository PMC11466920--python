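"""The four evaluation metrics on a worked confusion table and mask pair.

IoU, Dice and pixel accuracy come from per-image confusion counts; HD95 is
the 95th percentile of pooled boundary-to-boundary distances, robust to a few
stray boundary pixels where the classical Hausdorff distance is not.
"""

import numpy as np

from duoseg import ConfusionCounts, acc, dice, hd95, iou

c = ConfusionCounts(tp=3, fp=1, fn=2, tn=10)
print(f"TP=3 FP=1 FN=2 TN=10  ->  IoU {iou(c):.4f}, Dice {dice(c):.4f}, ACC {acc(c):.4f}")
print(f"identity check: 2*IoU/(1+IoU) = {2*iou(c)/(1+iou(c)):.4f} equals Dice")

pred = np.zeros((32, 32), np.uint8)
gt = np.zeros((32, 32), np.uint8)
yy, xx = np.mgrid[0:32, 0:32]
gt[(yy - 16) ** 2 + (xx - 16) ** 2 <= 64] = 1       # radius-8 disc
pred[(yy - 16) ** 2 + (xx - 18) ** 2 <= 64] = 1     # same disc shifted 2 px
print(f"disc vs 2-px-shifted disc: HD95 = {hd95(pred, gt):.2f} px "
      f"(full Hausdorff {hd95(pred, gt, percentile=100):.2f} px)")
print("with a pixel spacing in mm, distances are reported in mm:",
      f"{hd95(pred, gt, spacing=0.2):.2f} mm at 0.2 mm/px")
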