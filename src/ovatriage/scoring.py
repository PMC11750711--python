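"""Case-level malignancy scoring.

An image's risk of malignancy is the sum of its five malignant-category
probabilities; a case's malignancy score is the unweighted mean over its
images; a case is called malignant when its score strictly exceeds the
cut-off (default 0.5).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["image_malignancy", "case_score", "classify", "score_cases"]

#: columns of the malignant categories in the canonical 10-vector order
MALIGNANT_SLICE = slice(5, 10)
_PROB_TOL = 1e-6


def image_malignancy(probs) -> float:
    """Malignancy risk of one image: the sum of the 5 malignant-class entries.

    ``probs`` is a length-10 probability vector in canonical category order
    (five benign categories, then five malignant).
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (10,):
        raise ValueError(f"expected a length-10 probability vector, got shape {p.shape}")
    if (p < 0).any():
        raise ValueError("probability vector has negative entries")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"probability vector sums to {p.sum():.8f}, expected 1")
    return float(p[MALIGNANT_SLICE].sum())


def case_score(image_scores: Iterable[float]) -> float:
    """Case malignancy score: the arithmetic mean of its image scores."""
    s = np.asarray(list(image_scores), dtype=float)
    if s.size == 0:
        raise ValueError("case has no images")
    return float(s.mean())


def classify(score: float, cutoff: float = 0.5) -> int:
    """1 (malignant) iff the score strictly exceeds the cut-off, else 0.

    A score exactly at the cut-off classifies benign.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    return int(score > cutoff)


def score_cases(image_preds: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Aggregate an image-prediction table to case-level scores and calls.

    ``image_preds`` must hold case_id, image_id and p_1..p_10 columns.
    Returns one row per case: case_id, malignancy_score, n_images,
    prediction (binary call at ``cutoff``).
    """
    pcols = [f"p_{i + 1}" for i in range(10)]
    probs = image_preds[pcols].to_numpy(float)
    if (probs < -_PROB_TOL).any():
        raise ValueError("image prediction with negative probability")
    sums = probs.sum(axis=1)
    bad = np.abs(sums - 1.0) > _PROB_TOL
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"image prediction row {i} (case {image_preds['case_id'].iat[i]}) "
            f"sums to {sums[i]:.8f}"
        )
    img_scores = probs[:, MALIGNANT_SLICE].sum(axis=1)
    out = (
        pd.DataFrame({"case_id": image_preds["case_id"], "score": img_scores})
        .groupby("case_id", sort=True)
        .agg(malignancy_score=("score", "mean"), n_images=("score", "size"))
        .reset_index()
    )
    out["prediction"] = (out["malignancy_score"] > cutoff).astype(int)
    return out
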