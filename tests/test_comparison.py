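"""Reader-comparison statistics: matched sets, signed-rank exactness,
inverse-workload sampling, bootstrap machinery, ROC coherence, bivariate
random-effects summary, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from ovatriage import (
    auc,
    bivariate_summary,
    calibration_curve,
    examiner_sampling_weights,
    matched_cutoff,
    paired_scores,
    pooled_examiner_metrics,
    roc_confidence_band,
    roc_curve,
    wilcoxon_signed_rank,
)
from ovatriage.comparison import percentile_bootstrap


# ---------------------------------------------------------------------------
# paired matched-case metrics

def test_paired_scores_matched_set_semantics(small_cohort, small_scores):
    pairs = paired_scores(
        small_cohort["assessments"], small_scores, small_cohort["cases"],
        metric="f1", examiners=small_cohort["examiners"],
    )
    assert len(pairs) == small_cohort["examiners"]["examiner_id"].nunique()
    # n_cases per examiner equals the examiner's workload in the design
    workloads = small_cohort["design"]["examiner_id"].value_counts()
    for _, row in pairs.iterrows():
        assert row["n_cases"] == workloads[row["examiner_id"]]


def test_paired_scores_identical_calls_give_equal_metrics(small_cohort, small_scores):
    """An examiner whose calls equal the AI's predictions gets exactly the
    AI's metric on their case set."""
    assessments = small_cohort["assessments"].copy()
    pred = small_scores.set_index("case_id")["prediction"]
    one = assessments["examiner_id"] == "E000"
    assessments.loc[one, "call"] = assessments.loc[one, "case_id"].map(pred).to_numpy()
    pairs = paired_scores(
        assessments, small_scores, small_cohort["cases"], metric="f1"
    ).set_index("examiner_id")
    assert pairs.loc["E000", "examiner_metric"] == pytest.approx(
        pairs.loc["E000", "ai_metric"], abs=1e-12
    )


def test_paired_scores_disjoint_sets_differ(small_cohort, small_scores):
    pairs = paired_scores(
        small_cohort["assessments"], small_scores, small_cohort["cases"], "f1"
    )
    # matched-set semantics: the AI metric varies across examiners
    assert pairs["ai_metric"].nunique() > 1


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

def _enumeration_p(d):
    """Full 2^n enumeration of the signed-rank null, ties via midranks."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def test_wilcoxon_all_zero_convention():
    assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == (0.0, 1.0)


def test_wilcoxon_all_positive_exact():
    stat, p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
    assert stat == 21.0
    assert p == pytest.approx(2 / 64, abs=1e-12)


def test_wilcoxon_exact_matches_enumeration(rng):
    """Exact p equals the full 2^n enumeration for all n <= 12, with ties
    and zeros present."""
    for n in (3, 5, 8, 12):
        for _ in range(5):
            d = rng.integers(-4, 5, n).astype(float)
            if (d == 0).all():
                continue
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(_enumeration_p(d), abs=1e-12)


def test_wilcoxon_exact_matches_scipy_without_ties(rng):
    """On tie-free data scipy's exact method is an independent oracle."""
    for n in (14, 20, 25):
        d = rng.normal(size=n)
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)


def test_wilcoxon_large_n_normal_approximation(rng):
    d = rng.normal(0.3, 1.0, 60)
    _, p = wilcoxon_signed_rank(d)
    ref = stats.wilcoxon(
        d, zero_method="wilcox", correction=True, method="approx"
    ).pvalue
    assert p == pytest.approx(float(ref), abs=1e-12)


# ---------------------------------------------------------------------------
# inverse-workload sampling

def test_sampling_weights_forced_by_normalisation():
    design = pd.DataFrame({"case_id": [1, 1], "examiner_id": ["a", "b"]})
    w = examiner_sampling_weights(design, {"a": 100, "b": 300})
    assert w.set_index("examiner_id")["weight"].to_dict() == pytest.approx(
        {"a": 0.75, "b": 0.25}
    )


def test_sampling_weights_equal_workloads_uniform():
    design = pd.DataFrame({"case_id": [1, 1, 1], "examiner_id": list("abc")})
    w = examiner_sampling_weights(design, {"a": 50, "b": 50, "c": 50})
    assert np.allclose(w["weight"], 1 / 3)


def test_sampling_weights_missing_examiner_errors():
    design = pd.DataFrame({"case_id": [1], "examiner_id": ["a"]})
    with pytest.raises(ValueError):
        examiner_sampling_weights(design, {"b": 10})
    with pytest.raises(ValueError):
        examiner_sampling_weights(design.iloc[:0], {"a": 10})


def test_selection_counts_match_weight_expectation(rng):
    """Over many replicates, per-examiner selection totals match the
    expectation implied by the inverse-workload weights."""
    cases = list(range(40))
    design = pd.DataFrame(
        [(c, e) for c in cases for e in ("a", "b", "c")],
        columns=["case_id", "examiner_id"],
    )
    workloads = {"a": 40, "b": 120, "c": 240}
    w = examiner_sampling_weights(design, workloads)
    expected = w.groupby("examiner_id")["weight"].sum()

    from ovatriage.comparison import _sample_one_per_case

    sub = w.sort_values("case_id", kind="stable")
    codes = sub["case_id"].to_numpy()
    idx = _sample_one_per_case(codes, sub["weight"].to_numpy(), 40, 2500, rng)
    chosen = sub["examiner_id"].to_numpy()[idx]
    totals = pd.Series(chosen.ravel()).value_counts() / 2500
    for e in "abc":
        se = np.sqrt(expected[e])  # Poisson-ish scale per replicate
        assert abs(totals[e] - expected[e]) < 3 * se / np.sqrt(40)


def test_pooled_metrics_single_examiner_degenerate(small_cohort):
    """With one examiner per tier the pooled metrics equal that examiner's
    own metrics and the CI is degenerate."""
    from ovatriage import confusion, metric_set

    ex = small_cohort["examiners"]
    one = ex[ex["examiner_id"] == "E000"]
    sub = small_cohort["assessments"]
    sub = sub[sub["examiner_id"] == "E000"]
    pooled = pooled_examiner_metrics(
        sub, small_cohort["cases"], "expert", one, n_reps=200, seed=0
    )
    merged = sub.merge(small_cohort["cases"][["case_id", "label"]], on="case_id")
    own = metric_set(confusion(merged["call"], merged["label"]))
    assert pooled.loc["sensitivity", "estimate"] == pytest.approx(own.sensitivity)
    assert pooled.loc["sensitivity", "ci_lo"] == pooled.loc["sensitivity", "ci_hi"]


def test_pooled_metrics_deterministic_under_seed(small_cohort):
    kw = dict(
        assessments=small_cohort["assessments"], labels=small_cohort["cases"],
        tier="non-expert", examiners=small_cohort["examiners"], n_reps=150,
    )
    a = pooled_examiner_metrics(seed=5, **kw)
    b = pooled_examiner_metrics(seed=5, **kw)
    pd.testing.assert_frame_equal(a, b)


def test_pooled_metrics_warns_on_few_reps(small_cohort):
    with pytest.warns(UserWarning, match="n_reps"):
        pooled_examiner_metrics(
            small_cohort["assessments"], small_cohort["cases"], "expert",
            small_cohort["examiners"], n_reps=50, seed=0,
        )


# ---------------------------------------------------------------------------
# ROC machinery

def test_roc_curve_endpoints_and_perfect_separation():
    c = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert (c["fpr"].iloc[0], c["tpr"].iloc[0]) == (0.0, 0.0)
    assert (c["fpr"].iloc[-1], c["tpr"].iloc[-1]) == (1.0, 1.0)
    assert ((c["fpr"] == 0.0) & (c["tpr"] == 1.0)).any()


def test_roc_curve_total_ties_is_diagonal():
    c = roc_curve([0.5] * 10, [0, 1] * 5)
    assert np.trapezoid(c["tpr"], c["fpr"]) == pytest.approx(0.5, abs=1e-12)


def test_roc_curve_monotone_and_area_equals_auc(rng):
    """Coordinates are nondecreasing and the trapezoidal area equals the
    Mann-Whitney AUC on every input."""
    for n in (20, 40, 100):
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            continue
        s = rng.integers(0, 8, n) / 7.0
        c = roc_curve(s, y)
        assert (np.diff(c["fpr"]) >= 0).all()
        assert (np.diff(c["tpr"]) >= 0).all()
        area = np.trapezoid(c["tpr"], c["fpr"])
        assert area == pytest.approx(auc(s, y), abs=1e-12)


def test_roc_band_contains_point_curve(small_cohort, small_scores):
    merged = small_cohort["cases"].merge(small_scores, on="case_id")
    band = roc_confidence_band(
        merged["malignancy_score"], merged["label"], n_boot=300, grid=201, seed=3
    )
    inside = (band.lower <= band.point + 1e-9) & (band.point <= band.upper + 1e-9)
    assert inside.mean() >= 0.95
    assert (band.lower <= band.upper).all()


def test_roc_band_deterministic_and_validated(small_cohort, small_scores):
    merged = small_cohort["cases"].merge(small_scores, on="case_id")
    a = roc_confidence_band(merged["malignancy_score"], merged["label"],
                            n_boot=200, grid=51, seed=9)
    b = roc_confidence_band(merged["malignancy_score"], merged["label"],
                            n_boot=200, grid=51, seed=9)
    assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)
    with pytest.raises(ValueError):
        roc_confidence_band([0.1, 0.9], [0, 1], n_boot=50)


def test_matched_cutoff_trivial_cases():
    s = [0.1, 0.2, 0.8, 0.9]
    y = [0, 0, 1, 1]
    cut, sens, spec = matched_cutoff(s, y, {"specificity": 1.0})
    assert spec == 1.0 and sens == 1.0
    assert cut >= 0.2
    cut, sens, spec = matched_cutoff(s, y, {"specificity": 0.5})
    assert sens == 1.0 and spec >= 0.5


def test_matched_cutoff_exhaustive_scan_oracle(rng):
    s = rng.random(100)
    y = rng.integers(0, 2, 100)
    target = 0.75
    cut, sens, spec = matched_cutoff(s, y, {"specificity": target})
    # oracle: scan a fine grid of cutoffs
    best = None
    for c in np.concatenate([[0.0], np.sort(s)]):
        sp = np.mean(s[y == 0] <= c)
        sn = np.mean(s[y == 1] > c)
        if sp >= target and (best is None or (sp, -sn) < (best[0], -best[1])):
            best = (sp, sn, c)
    assert spec == pytest.approx(best[0], abs=1e-12)
    assert sens == pytest.approx(best[1], abs=1e-12)


def test_matched_cutoff_unattainable_and_invalid():
    with pytest.raises(ValueError):
        matched_cutoff([0.2, 0.8], [0, 1], {"sensitivity": 0.0})
    with pytest.raises(ValueError):
        matched_cutoff([0.2, 0.8], [0, 1], {"f1": 0.5})


# ---------------------------------------------------------------------------
# bivariate random-effects summary

def _simulate_examiner_counts(rng, m=33, n_pos=250, n_neg=350,
                              mean=(0.824, 0.8267), sd=0.4, corr=-0.3):
    mu = np.array([logit(mean[0]), logit(mean[1])])
    cov = np.array([[sd**2, corr * sd**2], [corr * sd**2, sd**2]])
    lat = expit(rng.multivariate_normal(mu, cov, size=m))
    tp = rng.binomial(n_pos, lat[:, 0])
    tn = rng.binomial(n_neg, lat[:, 1])
    return pd.DataFrame(
        {"tp": tp, "fn": n_pos - tp, "tn": tn, "fp": n_neg - tn}
    )


def test_bivariate_identical_examiners_degenerate(rng):
    counts = pd.DataFrame({"tp": [820] * 10, "fn": [180] * 10,
                           "tn": [830] * 10, "fp": [170] * 10})
    summ = bivariate_summary(counts)
    assert np.allclose(summ.between_cov, 0.0)
    assert summ.ellipse_axes[0] < 1e-6
    assert summ.contains(summ.mean_logit)


def test_bivariate_requires_three_examiners():
    counts = pd.DataFrame({"tp": [5, 6], "fn": [1, 2], "tn": [7, 8], "fp": [2, 1]})
    with pytest.raises(ValueError):
        bivariate_summary(counts)


def test_bivariate_zero_cell_continuity(rng):
    counts = pd.DataFrame({"tp": [10, 12, 9], "fn": [0, 2, 1],
                           "tn": [15, 14, 16], "fp": [1, 2, 0]})
    summ = bivariate_summary(counts)  # must not produce inf logits
    assert np.isfinite(summ.mean_logit).all()


def test_bivariate_negative_correlation_sign_recovery():
    """With a strongly negative simulated sens-spec correlation the
    estimated between-examiner off-diagonal is negative in the majority of
    replications."""
    rng = np.random.default_rng(77)
    signs = []
    for _ in range(60):
        counts = _simulate_examiner_counts(rng, sd=0.5, corr=-0.6)
        signs.append(bivariate_summary(counts).between_cov[0, 1] < 0)
    assert np.mean(signs) > 0.5


# ---------------------------------------------------------------------------
# bootstrap and calibration

def test_percentile_bootstrap_point_estimate_and_determinism(rng):
    x = rng.normal(10, 2, 300)
    est, lo, hi = percentile_bootstrap(x, np.mean, n_boot=400, seed=1)
    assert est == pytest.approx(x.mean())
    assert lo < est < hi
    est2, lo2, hi2 = percentile_bootstrap(x, np.mean, n_boot=400, seed=1)
    assert (est, lo, hi) == (est2, lo2, hi2)


def test_calibration_perfect_scores_on_identity():
    labels = [0] * 30 + [1] * 30
    scores = [0.0] * 30 + [1.0] * 30
    curve, mace = calibration_curve(scores, labels, n_bins=2)
    assert mace == pytest.approx(0.0, abs=1e-12)
    for _, row in curve.iterrows():
        assert row["mean_score"] == pytest.approx(row["observed"], abs=1e-12)


def test_calibration_constant_score_single_point():
    scores = [0.4] * 50
    labels = [1] * 20 + [0] * 30
    curve, mace = calibration_curve(scores, labels, n_bins=10)
    assert len(curve) == 1
    assert curve.loc[0, "mean_score"] == pytest.approx(0.4)
    assert curve.loc[0, "observed"] == pytest.approx(0.4)
    assert curve["count"].sum() == 50


def test_calibration_counts_partition_and_errors(small_cohort, small_scores):
    merged = small_cohort["cases"].merge(small_scores, on="case_id")
    curve, _ = calibration_curve(merged["malignancy_score"], merged["label"], 10)
    assert curve["count"].sum() == len(merged)
    assert ((curve["observed"] >= 0) & (curve["observed"] <= 1)).all()
    with pytest.raises(ValueError):
        calibration_curve([0.5, 0.6], [0, 1], n_bins=10)
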