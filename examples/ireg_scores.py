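"""The IREG regularity index on hand-picked class posteriors.

IREG condenses a classifier's posterior over the five phenotype classes
into one number between 0 (total degeneration) and 1 (healthy eye) by
weighting each class with its severity rank.
"""

import numpy as np

from ommaquant import CLASS_ORDER, ireg_score

print("class order:", CLASS_ORDER)
for cls in CLASS_ORDER:
    p = np.zeros(5)
    p[CLASS_ORDER.index(cls)] = 1.0
    print(f"  all mass on {cls:<12} -> IREG = {ireg_score(p):.2f}")

mixed = np.array([0.5, 0.0, 0.5, 0.0, 0.0])   # half WT, half modifier#1
print(f"  50% WT / 50% modifier#1 -> IREG = {ireg_score(mixed):.3f}")
uniform = np.full(5, 0.2)
print(f"  uniform posterior        -> IREG = {ireg_score(uniform):.2f}")
print()
print("Pure classes land on the severity gridlines 1, 0.75, 0.5, 0.25, 0;")
print("mixtures interpolate linearly because the index is affine in the")
print("probability vector.")
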