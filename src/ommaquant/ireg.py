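"""IREG — the eye-regularity index.

IREG maps a classifier's posterior over the five phenotype classes to a
single score in [0, 1] by weighting each class with its position in the
severity ordering WT < modifier#1 < modifier#2 < modifier#3 < SCA1:

    IREG = [4 P(WT) + 3 P(mod#1) + 2 P(mod#2) + 1 P(mod#3) + 0 P(SCA1)] / 4

A healthy eye scores 1, total degeneration 0, and the pure modifier
classes land exactly on 0.75 / 0.5 / 0.25.  The score is linear in the
probability vector, so mixtures interpolate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import CLASS_ORDER, TrainedClassifier, predict_probabilities
from .hog import HOGParams, featurize_dataset

#: Severity weights over CLASS_ORDER = (WT, gmr>SCA1, mod#1, mod#2, mod#3);
#: configurable, but the default encodes the severity ordering above.
DEFAULT_WEIGHTS: dict[str, float] = {
    "WT": 1.0,
    "modifier#1": 0.75,
    "modifier#2": 0.5,
    "modifier#3": 0.25,
    "gmr>SCA1": 0.0,
}


@dataclass
class IREGSummary:
    """Per-genotype IREG distributions with boxplot statistics."""

    scores: dict[str, np.ndarray]
    stats: dict[str, dict[str, float]]


def ireg_score(p, class_order=CLASS_ORDER, weights: dict[str, float] | None = None,
               *, atol: float = 1e-8) -> float:
    """Severity-weighted mean of a class-probability vector.

    The input must be a proper probability vector (non-negative, summing to
    1); malformed inputs raise instead of being silently renormalized, to
    surface upstream bugs.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (len(class_order),):
        raise ValueError(f"expected a length-{len(class_order)} probability vector")
    if (p < -atol).any() or abs(p.sum() - 1.0) > atol:
        raise ValueError("input is not a normalized probability vector "
                         f"(sum = {p.sum():.6g})")
    w = weights or DEFAULT_WEIGHTS
    return float(sum(w[c] * pi for c, pi in zip(class_order, p)))


def _box_stats(x: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "n": int(len(x)), "median": float(med), "q1": float(q1), "q3": float(q3),
        "min": float(x.min()), "max": float(x.max()),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
    }


def ireg_batch(model: TrainedClassifier, patches, genotypes,
               hog_params: HOGParams | None = None,
               weights: dict[str, float] | None = None,
               genotype_order=None) -> IREGSummary:
    """Featurize, predict and score a batch, grouped by genotype.

    ``genotype_order`` fixes the group order of the summary (defaults to
    first appearance); a requested genotype with no images is omitted from
    the summary with a warning.
    """
    genotypes = list(genotypes)
    feats = featurize_dataset(patches, genotypes, hog_params)
    probs = predict_probabilities(model, feats)
    values = np.array([ireg_score(row, model.class_order, weights) for row in probs])
    groups = list(genotype_order) if genotype_order is not None \
        else list(dict.fromkeys(genotypes))
    scores: dict[str, np.ndarray] = {}
    stats: dict[str, dict[str, float]] = {}
    for g in groups:
        mask = np.asarray(genotypes) == g if genotypes else np.array([], dtype=bool)
        if not mask.any():
            warnings.warn(f"genotype {g!r} has no images; omitted from summary")
            continue
        scores[g] = values[mask]
        stats[g] = _box_stats(values[mask])
    return IREGSummary(scores=scores, stats=stats)
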