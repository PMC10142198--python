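"""Decode one region's per-CpG differential states with the three-state HMM.

Builds a toy reference UMR whose last six CpGs gained 0.4 methylation in the
tumor cohort, estimates the HMM parameters from the deltas, and prints the
Viterbi state of every CpG.
"""

import numpy as np

from phumr import decode_region, estimate_params
from phumr.diffhmm import STATE_NAMES

rng = np.random.default_rng(5)

# tumor-minus-normal methylation difference per CpG: flat, then eroded
true_states = np.array([0] * 10 + [1] * 6)
deltas = np.where(true_states == 1, 0.4, 0.0) + rng.normal(0, 0.03, size=16)

params = estimate_params(deltas, region_ids=np.zeros(16, dtype=int))
print("state means (Hyper, Hypo, NoDiff):", np.round(params.state_means, 3))

path = decode_region(deltas, params)
for i, (d, s) in enumerate(zip(deltas, path)):
    marker = "<-- erosion border" if i == 10 else ""
    print(f"CpG {i:2d}  delta {d:+.3f}  {STATE_NAMES[s]:7s} {marker}")
# The printed states should flip from NoDiff to Hyper exactly at CpG 10:
# the HMM finds the hypermethylation border at single-CpG resolution.
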