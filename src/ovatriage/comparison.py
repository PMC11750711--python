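"""AI-vs-examiner comparison statistics.

Matched-case paired metrics, Wilcoxon signed-rank tests, pooled examiner
operating points under inverse-workload examiner sampling, percentile
bootstrap, ROC curves with bootstrap confidence bands, matched-cutoff
analysis, a bivariate random-effects summary of reader operating points on
the logit scale, and calibration curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve as _sk_roc_curve

from .metrics import ConfusionMatrix, MetricSet, confusion, metric_set

__all__ = [
    "paired_scores",
    "wilcoxon_signed_rank",
    "examiner_sampling_weights",
    "pooled_examiner_metrics",
    "percentile_bootstrap",
    "roc_curve",
    "RocBand",
    "roc_confidence_band",
    "matched_cutoff",
    "BivariateSummary",
    "bivariate_summary",
    "calibration_curve",
]

_METRIC_NAMES = (
    "sensitivity", "specificity", "accuracy", "ppv", "f1", "kappa", "mcc",
    "dor", "youden_j",
)


# ---------------------------------------------------------------------------
# paired matched-case metrics

def paired_scores(
    assessments: pd.DataFrame,
    ai_predictions: pd.DataFrame,
    labels: pd.DataFrame,
    metric: str = "f1",
    examiners: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """One row per examiner: their metric and the AI's metric on the exact
    set of cases that examiner assessed (matched case sets).

    ``ai_predictions`` must hold case_id and a binary ``prediction`` column;
    ``labels`` holds case_id and ``label``.  An examiner whose case set
    leaves the metric undefined is kept with a missing value and flagged.
    """
    if metric not in _METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    df = assessments.merge(labels[["case_id", "label"]], on="case_id", validate="m:1")
    df = df.merge(
        ai_predictions[["case_id", "prediction"]], on="case_id", validate="m:1"
    )
    tier_of: Mapping[str, str] = {}
    if examiners is not None:
        tier_of = dict(zip(examiners["examiner_id"], examiners["tier"]))
    rows = []
    for eid, sub in df.groupby("examiner_id", sort=True):
        m_ex = getattr(metric_set(confusion(sub["call"], sub["label"])), metric)
        m_ai = getattr(metric_set(confusion(sub["prediction"], sub["label"])), metric)
        rows.append(
            {
                "examiner_id": eid,
                "tier": tier_of.get(eid),
                "n_cases": len(sub),
                "examiner_metric": np.nan if m_ex is None else m_ex,
                "ai_metric": np.nan if m_ai is None else m_ai,
                "undefined": m_ex is None or m_ai is None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by the generating-function distribution of W+.

    Ties are allowed: midranks are doubled to integers and the null
    distribution of the doubled statistic is built by polynomial
    multiplication over all 2^n equiprobable sign assignments.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    differences: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded (all-zero input returns p = 1 by
    convention).  For n <= ``exact_max_n`` after zero removal the null
    distribution of W+ is enumerated exactly (ties handled by midranks);
    beyond that a normal approximation with tie correction and continuity
    correction is used.  Returns (W+, p).
    """
    d = np.asarray(differences, float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, alternative="two-sided",
        method="approx",
    )
    return w_plus, float(res.pvalue)


# ---------------------------------------------------------------------------
# inverse-workload examiner sampling

def examiner_sampling_weights(
    design: pd.DataFrame, workloads: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Per-case selection distribution over the case's eligible examiners,
    with probability inversely proportional to each examiner's workload
    (total cases assessed), normalised within case.

    ``design`` is a long (case_id, examiner_id) frame, already restricted to
    the tier of interest.  Raises if a case has no eligible examiner.
    """
    if len(design) == 0:
        raise ValueError("empty design: some case has no eligible examiner")
    w = pd.Series(workloads, dtype=float)
    df = design[["case_id", "examiner_id"]].copy()
    df["inv"] = df["examiner_id"].map(1.0 / w)
    if df["inv"].isna().any():
        missing = df.loc[df["inv"].isna(), "examiner_id"].unique()
        raise ValueError(f"no workload recorded for examiners {list(missing)}")
    df["weight"] = df["inv"] / df.groupby("case_id")["inv"].transform("sum")
    return df[["case_id", "examiner_id", "weight"]]


def _sample_one_per_case(
    case_codes: np.ndarray, weights: np.ndarray, n_cases: int,
    n_reps: int, rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised inverse-CDF draw of one row index per case per replicate.

    ``case_codes`` must be sorted, coding cases as 0..n_cases-1; weights are
    normalised within case.  Returns an (n_reps, n_cases) array of row
    indices into the design.
    """
    cum = np.cumsum(weights)
    seg_end = np.cumsum(np.bincount(case_codes, minlength=n_cases))
    seg_start = seg_end - np.bincount(case_codes, minlength=n_cases)
    # within-case cumulative in [0, 1), offset by case index
    cum_within = cum - np.where(seg_start > 0, cum[seg_start - 1], 0.0)[case_codes]
    glob = case_codes + np.minimum(cum_within, 1.0 - 1e-12)
    u = rng.random((n_reps, n_cases)) + np.arange(n_cases)
    return np.searchsorted(glob, u, side="left")


def _vectorised_metric_suite(
    tp: np.ndarray, fp: np.ndarray, tn: np.ndarray, fn: np.ndarray
) -> dict[str, np.ndarray]:
    """The metric suite on vectors of confusion counts (one entry per
    bootstrap replicate).  Degenerate denominators yield NaN/inf as in
    :func:`ovatriage.metrics.metric_set`."""
    with np.errstate(divide="ignore", invalid="ignore"):
        n = tp + fp + tn + fn
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ppv = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
        acc = (tp + tn) / n
        f1 = np.where(ppv + sens > 0, 2 * ppv * sens / (ppv + sens), 0.0)
        p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
        kappa = (acc - p_e) / (1.0 - p_e)
        denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.where(denom2 > 0, (tp * tn - fp * fn) / np.sqrt(denom2), 0.0)
        dor = np.where(
            fp * fn > 0, tp * tn / np.maximum(fp * fn, 1),
            np.where(tp * tn > 0, np.inf, np.nan),
        )
        j = sens + spec - 1.0
    return {
        "sensitivity": sens, "specificity": spec, "accuracy": acc, "ppv": ppv,
        "f1": f1, "kappa": kappa, "mcc": mcc, "dor": dor, "youden_j": j,
    }


def summarise_replicates(
    suite: dict[str, np.ndarray], level: float = 0.95
) -> pd.DataFrame:
    """Mean and percentile CI per metric over replicate values; non-finite
    replicate values (e.g. an infinite DOR) are excluded from both."""
    alpha = (1.0 - level) / 2.0
    rows = {}
    for name, vals in suite.items():
        finite = vals[np.isfinite(vals)]
        if finite.size:
            rows[name] = {
                "estimate": float(finite.mean()),
                "ci_lo": float(np.percentile(finite, 100 * alpha)),
                "ci_hi": float(np.percentile(finite, 100 * (1 - alpha))),
            }
        else:
            rows[name] = {"estimate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}
    return pd.DataFrame(rows).T[["estimate", "ci_lo", "ci_hi"]]


def pooled_examiner_metrics(
    assessments: pd.DataFrame,
    labels: pd.DataFrame,
    tier: str,
    examiners: pd.DataFrame,
    n_reps: int = 2000,
    seed=0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Pooled tier-level operating point with percentile CIs.

    Per replicate, one examiner is drawn for every case among those who
    assessed it, with probability inversely proportional to the examiner's
    workload (so high-volume examiners do not dominate the pooled figure),
    and the metric suite is computed on the selected calls.  The point
    estimate is the mean over replicates; the CI the (2.5, 97.5) percentiles
    at the default level.  Returns a frame indexed by metric with columns
    estimate, ci_lo, ci_hi.
    """
    import warnings

    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} is small for percentile CIs", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tier_ids = set(examiners.loc[examiners["tier"] == tier, "examiner_id"])
    sub = assessments[assessments["examiner_id"].isin(tier_ids)]
    if len(sub) == 0:
        raise ValueError(f"no assessments for tier {tier!r}")
    workloads = sub["examiner_id"].value_counts()
    wdf = examiner_sampling_weights(sub[["case_id", "examiner_id"]], workloads)
    sub = sub.merge(labels[["case_id", "label"]], on="case_id", validate="m:1")
    sub = sub.merge(wdf, on=["case_id", "examiner_id"])
    sub = sub.sort_values("case_id", kind="stable").reset_index(drop=True)
    codes, _ = pd.factorize(sub["case_id"], sort=False)
    n_cases = codes.max() + 1
    idx = _sample_one_per_case(
        codes, sub["weight"].to_numpy(), n_cases, n_reps, rng
    )
    calls = sub["call"].to_numpy()[idx]
    lab = sub["label"].to_numpy()[idx]
    tp = ((calls == 1) & (lab == 1)).sum(axis=1).astype(float)
    fp = ((calls == 1) & (lab == 0)).sum(axis=1).astype(float)
    tn = ((calls == 0) & (lab == 0)).sum(axis=1).astype(float)
    fn = ((calls == 0) & (lab == 1)).sum(axis=1).astype(float)
    suite = _vectorised_metric_suite(tp, fp, tn, fn)
    return summarise_replicates(suite, level=level)


def percentile_bootstrap(
    data: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 2000,
    seed=0,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Case-resampling percentile bootstrap of a statistic.

    Returns (point estimate on the full data, CI low, CI high), the CI from
    the (alpha/2, 1 - alpha/2) percentiles of the bootstrap distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.asarray(data)
    n = data.shape[0]
    if n == 0:
        raise ValueError("empty data")
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = statistic(data[rng.integers(0, n, size=n)])
    alpha = (1.0 - level) / 2.0
    return (
        float(statistic(data)),
        float(np.percentile(boot, 100 * alpha)),
        float(np.percentile(boot, 100 * (1 - alpha))),
    )


# ---------------------------------------------------------------------------
# ROC machinery

def roc_curve(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve over all distinct thresholds.

    Returns a frame with columns threshold, fpr, tpr, running from (0, 0)
    to (1, 1); the trapezoidal area equals the Mann-Whitney AUC.
    """
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, float),
                                  drop_intermediate=False)
    return pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})


def _interp_tpr_at_spec(curve: pd.DataFrame, spec_grid: np.ndarray) -> np.ndarray:
    spec = (1.0 - curve["fpr"].to_numpy())[::-1]  # ascending
    tpr = curve["tpr"].to_numpy()[::-1]
    return np.interp(spec_grid, spec, tpr)


@dataclass
class RocBand:
    """Pointwise bootstrap percentile band for sensitivity at each level of
    specificity."""

    spec_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    point: np.ndarray
    n_boot: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specificity": self.spec_grid,
                "sens_lower": self.lower,
                "sens_point": self.point,
                "sens_upper": self.upper,
            }
        )


def roc_confidence_band(
    scores,
    labels,
    n_boot: int = 2000,
    grid: int | np.ndarray = 1001,
    seed=0,
    level: float = 0.95,
) -> RocBand:
    """Pointwise ROC confidence band from case-level bootstrap.

    Each bootstrap resample's ROC curve is linearly interpolated onto a
    common specificity grid; the band holds the (2.5, 97.5) percentiles of
    the interpolated sensitivities at each grid point.  Degenerate
    single-class resamples are redrawn and counted.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    spec_grid = np.linspace(0.0, 1.0, grid) if np.isscalar(grid) else np.asarray(grid)
    point = _interp_tpr_at_spec(roc_curve(s, y), spec_grid)
    n = s.size
    boot = np.empty((n_boot, spec_grid.size))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            n_redrawn += 1
        boot[b] = _interp_tpr_at_spec(roc_curve(s[idx], y[idx]), spec_grid)
    alpha = (1.0 - level) / 2.0
    lower = np.percentile(boot, 100 * alpha, axis=0)
    upper = np.percentile(boot, 100 * (1 - alpha), axis=0)
    return RocBand(spec_grid, lower, upper, point, n_boot, n_redrawn)


def matched_cutoff(
    scores, labels, target: Mapping[str, float]
) -> tuple[float, float, float]:
    """Operating point matched to a reference sensitivity or specificity.

    ``target`` is ``{"specificity": s}`` or ``{"sensitivity": s}``.  Among
    the cutoffs whose constrained coordinate is at least the target, the one
    closest to the target is chosen (ties broken toward the higher
    unconstrained coordinate).  Returns (cutoff, sensitivity, specificity)
    at the chosen cutoff; a case is called malignant when its score strictly
    exceeds the cutoff.
    """
    if len(target) != 1 or next(iter(target)) not in ("sensitivity", "specificity"):
        raise ValueError("target must be {'sensitivity': s} or {'specificity': s}")
    which, t = next(iter(target.items()))
    if not 0.0 < t <= 1.0:
        raise ValueError("target must be in (0, 1]")
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # candidate cutoffs: 0 and every distinct score (strict > makes these
    # exhaust all achievable operating points)
    cand = np.unique(np.concatenate([[0.0], s]))
    sens = np.array([(s[y == 1] > c).mean() for c in cand])
    spec = np.array([(s[y == 0] > c).mean() for c in cand])
    spec = 1.0 - spec
    con, unc = (spec, sens) if which == "specificity" else (sens, spec)
    ok = con >= t - 1e-12
    if not ok.any():
        raise ValueError(f"target {which} {t} unattainable")
    best = np.lexsort((-unc[ok], con[ok]))[0]
    i = np.flatnonzero(ok)[best]
    return float(cand[i]), float(sens[i]), float(spec[i])


# ---------------------------------------------------------------------------
# bivariate random-effects reader summary

@dataclass
class BivariateSummary:
    """Method-of-moments bivariate random-effects summary of per-examiner
    (sensitivity, specificity) on the logit scale."""

    mean_logit: np.ndarray            # (logit sens, logit spec)
    between_cov: np.ndarray           # 2x2, between-examiner
    cov_of_mean: np.ndarray           # 2x2, sampling covariance of the mean
    n_examiners: int
    ellipse_level: float = 0.95
    #: semi-axis lengths and rotation angle (radians) of the confidence
    #: ellipse for the mean on the logit scale
    ellipse_axes: tuple[float, float] = field(default=(0.0, 0.0))
    ellipse_angle: float = 0.0

    @property
    def sens(self) -> float:
        return float(expit(self.mean_logit[0]))

    @property
    def spec(self) -> float:
        return float(expit(self.mean_logit[1]))

    def contains(self, point_logit) -> bool:
        """Whether a logit-scale point lies inside the confidence ellipse."""
        d = np.asarray(point_logit, float) - self.mean_logit
        if not d.any():
            return True
        q = d @ np.linalg.pinv(self.cov_of_mean) @ d
        return bool(q <= stats.chi2.ppf(self.ellipse_level, 2))

    def to_dict(self) -> dict:
        return {
            "mean_logit_sens": float(self.mean_logit[0]),
            "mean_logit_spec": float(self.mean_logit[1]),
            "sens": self.sens,
            "spec": self.spec,
            "between_cov": self.between_cov.tolist(),
            "cov_of_mean": self.cov_of_mean.tolist(),
            "n_examiners": self.n_examiners,
            "ellipse_axes": list(self.ellipse_axes),
            "ellipse_angle": self.ellipse_angle,
            "ellipse_level": self.ellipse_level,
        }


def bivariate_summary(
    counts: pd.DataFrame, level: float = 0.95
) -> BivariateSummary:
    """Bivariate random-effects summary of reader operating points.

    ``counts`` has one row per examiner with columns tp, fn, tn, fp.  Each
    examiner's (sensitivity, specificity) is logit-transformed (0.5 added to
    the cells of any zero margin) with delta-method within-examiner
    variances 1/x + 1/(n-x); the between-examiner covariance is estimated by
    method of moments (sample covariance of the logits minus the mean
    within-examiner variance on the diagonal, floored at 0).  The covariance
    of the mean is the sample covariance of the logits divided by the number
    of examiners, and the 95% confidence ellipse follows from its
    chi-square(2) quantile.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 examiners")
    tp = counts["tp"].to_numpy(float)
    fn = counts["fn"].to_numpy(float)
    tn = counts["tn"].to_numpy(float)
    fp = counts["fp"].to_numpy(float)
    if ((tp + fn) == 0).any() or ((tn + fp) == 0).any():
        raise ValueError("every examiner must have assessed both classes")

    def _logit_and_var(x, nx):
        zero = (x == 0) | (nx == 0)
        x = np.where(zero, x + 0.5, x)
        nx = np.where(zero, nx + 0.5, nx)
        return np.log(x / nx), 1.0 / x + 1.0 / nx

    ls, vs = _logit_and_var(tp, fn)
    lp, vp = _logit_and_var(tn, fp)
    m = len(counts)
    pts = np.column_stack([ls, lp])
    mean = pts.mean(axis=0)
    samp = np.cov(pts, rowvar=False)
    between = samp.copy()
    between[0, 0] = max(0.0, samp[0, 0] - vs.mean())
    between[1, 1] = max(0.0, samp[1, 1] - vp.mean())
    # keep the floored matrix positive semi-definite
    lim = math.sqrt(between[0, 0] * between[1, 1])
    between[0, 1] = between[1, 0] = float(np.clip(between[0, 1], -lim, lim))
    cov_mean = samp / m
    evals, evecs = np.linalg.eigh(cov_mean)
    c = stats.chi2.ppf(level, 2)
    axes = tuple(float(math.sqrt(max(ev, 0.0) * c)) for ev in evals[::-1])
    angle = float(math.atan2(evecs[1, -1], evecs[0, -1]))
    return BivariateSummary(
        mean_logit=mean, between_cov=between, cov_of_mean=cov_mean,
        n_examiners=m, ellipse_level=level, ellipse_axes=axes,
        ellipse_angle=angle,
    )


# ---------------------------------------------------------------------------
# calibration

def calibration_curve(
    scores, labels, n_bins: int = 10
) -> tuple[pd.DataFrame, float]:
    """Equal-frequency calibration curve and mean absolute calibration error.

    Returns (per-bin frame with mean_score, observed frequency and count;
    count-weighted mean absolute deviation between them).
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.size < n_bins:
        raise ValueError("fewer cases than bins")
    if np.unique(s).size == 1:
        bins = np.zeros(s.size, int)  # constant scores: one bin
    else:
        bins = pd.qcut(s, n_bins, duplicates="drop")
    df = pd.DataFrame({"score": s, "label": y, "bin": bins})
    out = (
        df.groupby("bin", observed=True)
        .agg(mean_score=("score", "mean"), observed=("label", "mean"),
             count=("label", "size"))
        .reset_index(drop=True)
    )
    mace = float(
        (np.abs(out["mean_score"] - out["observed"]) * out["count"]).sum()
        / out["count"].sum()
    )
    return out, mace
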