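"""Case-level diagnostic-performance metrics.

Conventions for degenerate inputs follow the usual diagnostic-accuracy
practice: proportions with a zero denominator are *explicitly missing*
(``None``), never silently 0; the diagnostic odds ratio is ``+inf`` when
only the off-diagonal cells vanish (an optional Haldane-Anscombe 0.5
correction is available); MCC with a zero denominator factor is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "confusion",
    "metric_set",
    "brier",
    "auc",
    "jeffreys_ci",
    "reconstruct_confusion",
    "grouped_metrics",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 case-level counts: malignant is the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """The diagnostic metric suite; proportions are fractions in [0, 1].

    Metrics whose denominator is empty are ``None``.  ``youden_j`` satisfies
    sensitivity + specificity - 1 and ``f1`` the harmonic-mean identity with
    PPV and sensitivity whenever those terms are defined.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    ppv: Optional[float]
    f1: Optional[float]
    kappa: Optional[float]
    mcc: Optional[float]
    dor: Optional[float]
    youden_j: Optional[float]
    brier: Optional[float] = None
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_percent_dict(self, ndigits: int = 2) -> dict:
        """Report proportions as percentages rounded to ``ndigits`` decimals,
        matching the conventional presentation of diagnostic tables."""
        pct = {"sensitivity", "specificity", "accuracy", "ppv", "f1", "youden_j", "auc"}
        out = {}
        for k, v in asdict(self).items():
            if v is None:
                out[k] = None
            elif k in pct:
                out[k] = round(100.0 * v, ndigits)
            elif k == "dor":
                out[k] = v if math.isinf(v) else round(v, 2)
            else:
                out[k] = round(v, 3)
        return out


def confusion(predictions, labels) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix from aligned binary vectors."""
    p = np.asarray(predictions, int)
    y = np.asarray(labels, int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    if not (np.isin(p, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("predictions and labels must be binary")
    return ConfusionMatrix(
        tp=int(((p == 1) & (y == 1)).sum()),
        fp=int(((p == 1) & (y == 0)).sum()),
        tn=int(((p == 0) & (y == 0)).sum()),
        fn=int(((p == 0) & (y == 1)).sum()),
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def metric_set(cm: ConfusionMatrix, haldane: bool = False) -> MetricSet:
    """Compute the full metric suite from 2x2 counts.

    F1 = 2 * PPV * sens / (PPV + sens); Cohen's kappa uses marginal-product
    chance agreement; MCC = (tp*tn - fp*fn) / sqrt of the four marginal
    products (0 if any marginal vanishes); DOR = tp*tn / (fp*fn), ``+inf``
    when fp*fn = 0 with tp*tn > 0, or with a 0.5 Haldane-Anscombe correction
    on every cell when ``haldane``; Youden's J = sens + spec - 1.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    n = cm.total
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    acc = (tp + tn) / n

    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2.0 * ppv * sens / (ppv + sens)
    elif ppv is not None and sens is not None:
        f1 = 0.0
    else:
        f1 = None

    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (acc - p_e) / (1.0 - p_e) if p_e < 1.0 else None

    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 > 0 else 0.0

    if haldane:
        dor: Optional[float] = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    elif fp * fn > 0:
        dor = (tp * tn) / (fp * fn)
    elif tp * tn > 0:
        dor = math.inf
    else:
        dor = None

    j = sens + spec - 1.0 if sens is not None and spec is not None else None
    return MetricSet(
        sensitivity=sens, specificity=spec, accuracy=acc, ppv=ppv, f1=f1,
        kappa=kappa, mcc=mcc, dor=dor, youden_j=j,
    )


def brier(scores, labels) -> float:
    """Mean squared difference between predicted risk and the 0/1 outcome."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    return float(np.mean((s - y) ** 2))


def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney concordance probability
    P(score+ > score-) + 0.5 * P(tie) over all positive-negative pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(s)
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def jeffreys_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys Bayesian interval for a binomial proportion.

    Equal-tailed quantiles of the Beta(x + 1/2, n - x + 1/2) posterior, with
    the boundary convention that the lower bound is 0 when x = 0 and the
    upper bound is 1 when x = n.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("need 0 <= successes <= n with n > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    post = stats.beta(successes + 0.5, n - successes + 0.5)
    lo = 0.0 if successes == 0 else float(post.ppf(alpha / 2.0))
    hi = 1.0 if successes == n else float(post.ppf(1.0 - alpha / 2.0))
    return lo, hi


def reconstruct_confusion(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Rebuild integer 2x2 counts from printed sensitivity/specificity
    percentages and the class composition.

    tp is the nearest integer to sens * n_pos (tn likewise); an exact .5
    rounding ambiguity raises, since the printed value then fails to pin
    down the count.
    """
    if not (0.0 <= sensitivity <= 100.0 and 0.0 <= specificity <= 100.0):
        raise ValueError("sensitivity/specificity must be percentages in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")

    def _nearest(frac_pct: float, n: int, name: str) -> int:
        x = frac_pct / 100.0 * n
        if abs(x - math.floor(x) - 0.5) < 1e-9:
            raise ValueError(
                f"{name} * n = {x}: exact .5 rounding ambiguity; "
                "the printed value does not determine the count"
            )
        return int(round(x))

    tp = _nearest(sensitivity, n_pos, "sensitivity")
    tn = _nearest(specificity, n_neg, "specificity")
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


def grouped_metrics(
    predictions, labels, groups, haldane: bool = False
) -> pd.DataFrame:
    """Per-subgroup metric suites from aligned prediction/label/group vectors.

    Returns one row per subgroup with the confusion counts and the metric
    suite; metrics undefined in a single-class subgroup are missing (NaN).
    """
    df = pd.DataFrame(
        {"prediction": np.asarray(predictions, int),
         "label": np.asarray(labels, int),
         "group": np.asarray(groups)}
    )
    rows = []
    for key, sub in df.groupby("group", sort=True):
        cm = confusion(sub["prediction"], sub["label"])
        ms = metric_set(cm, haldane=haldane).to_dict()
        ms.pop("brier")  # score-based metrics are not defined from calls
        ms.pop("auc")
        rows.append(
            {"group": key, "n": cm.total, "tp": cm.tp, "fp": cm.fp,
             "tn": cm.tn, "fn": cm.fn,
             **{k: (np.nan if v is None else v) for k, v in ms.items()}}
        )
    return pd.DataFrame(rows)
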