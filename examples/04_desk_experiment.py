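"""The full desk-scale experiment: simulate 60 phantoms, adapt, evaluate.

Reproduces the package's reference protocol end to end (about 3-5 CPU
minutes): an 80/10/10 split, 300 adaptation steps of the decoder behind a
frozen tiny backbone, then held-out evaluation through the automatic
prompting inference path. Reports tumor overlap metrics and needle
localization in millimetres (0.1 mm/px calibration).
"""

from sonoseg.experiments import run_desk_experiment

res = run_desk_experiment(seed=0, n=60, steps=300)

print(f"adapted on {res.n_train} phantoms, evaluated on {res.n_test} held out")
print(f"loss {res.loss_initial:.3f} -> {res.loss_final:.3f} "
      f"({100 * res.loss_ratio:.0f}% of initial)\n")

t = res.tumor_report.aggregates
print("tumor segmentation (held out):")
print(f"  Dice {t['dice']['mean']:.3f} ± {t['dice']['std']:.3f}   "
      f"IoU {t['iou']['mean']:.3f}   precision {t['precision']['mean']:.3f}   "
      f"recall {t['recall']['mean']:.3f}")

n = res.needle_report.aggregates
print("needle localization (held out):")
print(f"  MHD {n['mhd_mm']['mean']:.3f} mm   TE {n['te_mm']['mean']:.3f} mm   "
      f"NLSR {n['nlsr_pct']['value']:.0f}%   NLR {n['nlr']['mean']:.3f}")
# NLSR 100% means every held-out frame's prediction overlaps more than
# half of the thinner of the two needle masks; MHD/TE well under 1 mm
# indicate sub-millimetre localization at this calibration.
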