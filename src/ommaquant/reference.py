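"""Published study data usable as inputs.

The original study evaluated four classifiers on a 75-image test split of
308 bright-field eye photographs and printed the resulting confusion
matrices (each cell holding four counts, one per classifier).  Those counts
are reproduced here so the evaluation statistics can be recomputed without
the image data.  Rows are predicted classes, columns reference classes, in
the canonical order (WT, gmr>SCA1, modifier#1, modifier#2, modifier#3).
"""

from __future__ import annotations

import numpy as np

from .classify import CLASS_ORDER
from .metrics import ConfusionMatrix

_SVM = [
    [20, 0, 1, 0, 0],
    [0, 11, 0, 0, 0],
    [0, 0, 12, 0, 0],
    [0, 0, 0, 14, 0],
    [0, 0, 0, 1, 16],
]
_DT = [
    [16, 2, 4, 0, 4],
    [2, 7, 2, 1, 2],
    [0, 0, 7, 0, 0],
    [1, 0, 0, 12, 3],
    [1, 2, 0, 2, 7],
]
_ADABOOST = [
    [20, 2, 3, 0, 3],
    [0, 7, 0, 1, 3],
    [0, 2, 10, 0, 0],
    [0, 0, 0, 11, 0],
    [0, 0, 0, 3, 10],
]
_RF = [
    [20, 2, 1, 1, 1],
    [0, 8, 0, 0, 0],
    [0, 0, 11, 0, 0],
    [0, 0, 1, 12, 0],
    [0, 1, 0, 2, 15],
]

#: Published test-set confusion matrices keyed by classifier kind.
REPORTED_CONFUSIONS: dict[str, ConfusionMatrix] = {
    kind: ConfusionMatrix(np.array(m), CLASS_ORDER)
    for kind, m in (("svm_rbf", _SVM), ("dt", _DT),
                    ("adaboost_dt", _ADABOOST), ("rf", _RF))
}

#: Study per-class sample sizes (WT, gmr>SCA1, mod#1, mod#2, mod#3).
STUDY_CLASS_SIZES: dict[str, int] = dict(zip(CLASS_ORDER, (82, 44, 55, 62, 65)))
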