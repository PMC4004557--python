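"""Choose a binarization threshold by maximum second-order entropy.

Builds a bimodal image (modes at gray levels 3 and 12 of 15 plus 5% salt),
computes the co-occurrence matrix of right/below transitions, the per-
threshold object/background transition entropies, and the maximising
threshold.
"""

import numpy as np

import retseg
from retseg.io import GrayImage

img, high_mode = retseg.generate_bimodal(seed=6)
q = retseg.quantize(GrayImage(img), L=15)
C = retseg.cooccurrence(q)
print(f"co-occurrence transitions counted: {int(C.counts.sum())}")

profile = retseg.entropy_curve(C)
t_opt = retseg.optimal_threshold(profile)
print("H_T(t):", np.round(profile.h_total, 2))
print(f"optimal threshold t* = {t_opt}  (modes sit at levels 3 and 12)")

mask = retseg.binarize(q, t_opt, scale=1.0)
err = (mask != high_mode).mean()
print(f"binarizing at t* recovers the bright mode with {err:.1%} pixel error")
print("The threshold maximises the summed within-object and within-")
print("background transition entropies, landing between the two modes.")
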