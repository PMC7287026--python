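"""Recompute evaluation metrics from the published confusion matrices.

The original study printed the predicted-by-reference count tables of four
classifiers evaluated on 75 held-out eye images.  Those counts fully
determine the global accuracy, its exact binomial confidence interval and
Cohen's kappa — so the statistics can be verified without any image data.
"""

from ommaquant import accuracy_with_ci, cohen_kappa
from ommaquant.reference import REPORTED_CONFUSIONS

print(f"{'classifier':<14} {'accuracy':>8} {'95% CI':>16} {'kappa':>7}")
for kind, cm in REPORTED_CONFUSIONS.items():
    acc, lo, hi = accuracy_with_ci(cm)
    kappa = cohen_kappa(cm)
    print(f"{kind:<14} {acc:8.3f}  ({lo:.3f}-{hi:.3f}) {kappa:7.3f}")

print()
print("Accuracy is the diagonal fraction of each 75-image test table; the")
print("interval is Clopper-Pearson exact binomial; kappa corrects the")
print("agreement for chance given the row/column marginals.")
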