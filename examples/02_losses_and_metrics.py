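"""The composite objective and the needle-localization metrics on a toy pair.

Prints the weighted BCE + Dice + Focal loss of an untrained prediction,
then scores a slightly shifted needle mask with the geometric metrics:
MHD (mean nearest-neighbor mismatch), TE (center-to-line distance error),
NLSR (overlap success) and NLR (length ratio).
"""

import numpy as np

from sonoseg import (LossConfig, mhd, nlr, nlsr, targeting_error, total_loss)
from sonoseg.metrics import mask_points

rng = np.random.default_rng(0)

# --- composite loss on random logits vs a small square target --------------
target = np.zeros((32, 32))
target[12:20, 12:20] = 1.0
logits = rng.normal(scale=0.5, size=(32, 32))
loss, parts = total_loss(logits, target, LossConfig())
print(f"total loss {float(loss):.4f}  "
      f"(bce {parts['bce']:.4f}, dice {parts['dice']:.4f}, focal {parts['focal']:.4f})")
# total = 0.3*bce + 0.4*dice + 0.3*focal; random logits sit near ln2 BCE.

# --- needle metrics on a 4-px-shifted prediction ----------------------------
gt = np.zeros((256, 256), bool)
pred = np.zeros((256, 256), bool)
gt[100, 20:236] = True       # true needle: row 100
pred[104, 20:230] = True     # predicted: 4 px deeper, slightly short
spacing = 0.1                # mm per pixel

print(f"MHD  {mhd(mask_points(pred), mask_points(gt), spacing):.3f} mm "
      "(max of the two directed mean nearest-neighbor distances)")
print(f"TE   {targeting_error(gt, pred, (256, 256), spacing):.3f} mm "
      "(|center-to-line distance difference|)")
print(f"NLSR {'success' if nlsr(gt, pred) else 'failure'} "
      "(overlap > half the smaller mask)")
print(f"NLR  {nlr(gt, pred):.3f} (predicted/true length; 1 is ideal)")
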