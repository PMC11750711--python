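"""Synthetic multi-center cohort generator.

Produces cases, examiner panels, review designs, examiner assessments and
AI image-level predictions with the statistical structure the downstream
analyses assume:

- every case carries a latent scalar *difficulty* (standard normal, larger =
  harder) shared by all simulators, inducing realistic error correlation
  between examiners and between examiners and the AI;
- examiner correctness follows a ceiling-probit link in difficulty whose
  intercept is calibrated in closed form so that the marginal sensitivity /
  specificity of each examiner equals their latent operating point exactly;
- examiner confidence (certain / probable / uncertain) is a two-threshold
  discretisation of noisily perceived difficulty, so accuracy is monotone
  decreasing from certain to uncertain;
- AI image scores are exact posterior probabilities under a two-component
  Gaussian latent-signal model, so the "calibrated" mode is calibrated by
  construction; temperature scaling produces the miscalibrated modes.
"""

from __future__ import annotations

import enum
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .config import CohortConfig, stage_rng

__all__ = [
    "HistologyCategory",
    "CATEGORY_CODES",
    "BENIGN_CODES",
    "MALIGNANT_CODES",
    "generate_cases",
    "generate_examiner_panel",
    "assign_reviews",
    "simulate_assessments",
    "simulate_ai_predictions",
    "generate_cohort",
]


class HistologyCategory(enum.Enum):
    """The ten histological categories, five benign and five malignant."""

    ENDOMETRIOMA = "endometrioma"
    DERMOID = "dermoid"
    OTHER_COMMON_BENIGN = "other_common_benign"
    SOLID_BENIGN = "solid_benign"
    CYSTADENOFIBROMA = "cystadenofibroma"
    BORDERLINE_SEROUS = "borderline_serous"
    BORDERLINE_MUCINOUS = "borderline_mucinous"
    CANCER_EPITHELIAL = "cancer_epithelial"
    CANCER_NONEPITHELIAL = "cancer_nonepithelial"
    METASTASIS = "metastasis"

    @property
    def is_malignant(self) -> bool:
        """Binary class; borderline tumors count as malignant."""
        return self in _MALIGNANT_SET


BENIGN_CODES = [
    "endometrioma", "dermoid", "other_common_benign", "solid_benign",
    "cystadenofibroma",
]
MALIGNANT_CODES = [
    "borderline_serous", "borderline_mucinous", "cancer_epithelial",
    "cancer_nonepithelial", "metastasis",
]
#: canonical category order; the last five are the malignant ones
CATEGORY_CODES = BENIGN_CODES + MALIGNANT_CODES
_MALIGNANT_SET = frozenset(HistologyCategory(c) for c in MALIGNANT_CODES)


def _rng_for(seed, stage: str) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return stage_rng(seed, stage)


def _draw_image_counts(rng: np.random.Generator, n: int, cfg: CohortConfig) -> np.ndarray:
    # n_images = 1 + NegBin(r, p); defaults give quartiles (3, 4, 6)
    r, m = cfg.image_count_r, cfg.image_count_mean
    p = r / (r + m)
    return 1 + rng.negative_binomial(r, p, size=n)


def generate_cases(config: CohortConfig, seed) -> pd.DataFrame:
    """Generate the case table with latent per-case difficulty.

    Returns a frame with columns case_id, center_id, histology, label, age,
    exam_year, us_system, management, n_images and the latent ``difficulty``
    (standard normal, larger = harder) shared by all downstream simulators.
    """
    config.validate()
    rng = _rng_for(seed, "cases")
    n = config.n_cases

    codes = list(config.category_probs)
    probs = np.array([config.category_probs[c] for c in codes], float)
    probs = probs / probs.sum()

    conservative = rng.random(n) < config.conservative_fraction
    histology = np.array(codes, object)[rng.choice(len(codes), size=n, p=probs)]
    if conservative.any():
        # conservatively managed lesions are benign by follow-up
        benign_idx = [i for i, c in enumerate(codes) if c in BENIGN_CODES]
        bp = probs[benign_idx]
        bp = bp / bp.sum()
        n_cons = int(conservative.sum())
        histology[conservative] = np.array(codes, object)[
            np.array(benign_idx)[rng.choice(len(benign_idx), size=n_cons, p=bp)]
        ]
    label = np.array([c in MALIGNANT_CODES for c in histology], int)

    age_mean = np.where(label == 1, config.age_mean_malignant, config.age_mean_benign)
    age = np.clip(rng.normal(age_mean, config.age_sd), *config.age_range).round(1)

    sys_names = list(config.us_system_probs)
    sys_p = np.array([config.us_system_probs[s] for s in sys_names], float)
    sys_p = sys_p / sys_p.sum()

    y0, y1 = config.exam_year_range
    df = pd.DataFrame(
        {
            "case_id": np.arange(n),
            "center_id": np.repeat(
                [f"C{i + 1:02d}" for i in range(config.n_centers)],
                config.cases_per_center,
            ),
            "histology": histology,
            "label": label,
            "age": age,
            "exam_year": rng.integers(y0, y1 + 1, size=n),
            "us_system": np.array(sys_names, object)[
                rng.choice(len(sys_names), size=n, p=sys_p)
            ],
            "management": np.where(conservative, "conservative", "surgery"),
            "n_images": _draw_image_counts(rng, n, config),
            "difficulty": rng.standard_normal(n),
        }
    )
    return df


def generate_examiner_panel(config: CohortConfig, seed) -> pd.DataFrame:
    """Draw examiner profiles from a bivariate logit-normal per tier.

    Latent (sensitivity, specificity) pairs are ``expit`` of a bivariate
    normal on the logit scale with tier-specific means and a shared
    between-examiner covariance (s.d. ``examiner_logit_sd``, correlation
    ``examiner_logit_corr``; negative by default, reflecting the usual
    threshold trade-off between sensitivity and specificity).
    """
    config.validate()
    rng = _rng_for(seed, "examiners")
    sd, rho = config.examiner_logit_sd, config.examiner_logit_corr
    cov = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])
    if np.linalg.eigvalsh(cov).min() < -1e-12:
        raise ValueError("examiner covariance is not positive semi-definite")

    rows = []
    tiers = [
        ("expert", config.n_experts, config.expert_sens, config.expert_spec),
        ("non-expert", config.n_nonexperts, config.nonexpert_sens, config.nonexpert_spec),
    ]
    centers = [f"C{i + 1:02d}" for i in range(config.n_centers)]
    eid = 0
    hi = config.examiner_ceiling - 1e-9
    for tier, n_tier, sens, spec in tiers:
        mean = np.array([logit(sens), logit(spec)])
        draws = rng.multivariate_normal(mean, cov, size=n_tier)
        latent = np.clip(expit(draws), 1e-9, hi)
        home = [centers[i % len(centers)] for i in rng.permutation(n_tier)]
        prop = rng.lognormal(0.0, config.propensity_sd, size=n_tier)
        for i in range(n_tier):
            rows.append(
                {
                    "examiner_id": f"E{eid:03d}",
                    "tier": tier,
                    "home_center": home[i],
                    "latent_sens": latent[i, 0],
                    "latent_spec": latent[i, 1],
                    "propensity": prop[i],
                }
            )
            eid += 1
    return pd.DataFrame(rows)


def assign_reviews(
    cases: pd.DataFrame,
    examiners: pd.DataFrame,
    config: CohortConfig,
    seed,
) -> pd.DataFrame:
    """Build the review design: which examiners assess which cases.

    Each case receives a panel of at least ``min_experts_per_case`` experts
    and ``min_nonexperts_per_case`` non-experts drawn without replacement
    among examiners from other centers, with selection probability
    proportional to each examiner's review propensity (so per-examiner
    workloads vary).  Returns a long frame (case_id, examiner_id).

    Raises ``ValueError`` if any case has fewer eligible external examiners
    of a tier than that tier's minimum.
    """
    rng = _rng_for(seed, "design")
    out_case, out_exam = [], []
    for tier, kmin, kmean, kmax in [
        ("expert", config.min_experts_per_case, config.experts_per_case_mean,
         config.experts_per_case_max),
        ("non-expert", config.min_nonexperts_per_case, config.nonexperts_per_case_mean,
         config.nonexperts_per_case_max),
    ]:
        ex = examiners[examiners["tier"] == tier].reset_index(drop=True)
        home = ex["home_center"].to_numpy()
        logw = np.log(ex["propensity"].to_numpy(float))
        eligible = cases["center_id"].to_numpy()[:, None] != home[None, :]
        n_eligible = eligible.sum(axis=1)
        if (n_eligible < kmin).any():
            bad = cases.loc[n_eligible < kmin, "center_id"].unique()
            raise ValueError(
                f"infeasible review design: centers {list(bad)} have fewer than "
                f"{kmin} external {tier} examiners"
            )
        n_cases = len(cases)
        sizes = np.clip(
            np.rint(rng.normal(kmean, config.panel_size_sd, size=n_cases)),
            kmin, kmax,
        ).astype(int)
        sizes = np.minimum(sizes, n_eligible)
        # Efraimidis-Spirakis: Gumbel-perturbed log-weights give weighted
        # sampling without replacement via top-k keys
        keys = logw[None, :] + rng.gumbel(size=(n_cases, len(ex)))
        keys[~eligible] = -np.inf
        order = np.argsort(-keys, axis=1)
        eids = ex["examiner_id"].to_numpy(object)
        cids = cases["case_id"].to_numpy()
        for i in range(n_cases):
            chosen = order[i, : sizes[i]]
            out_case.extend([cids[i]] * sizes[i])
            out_exam.extend(eids[chosen])
    design = pd.DataFrame({"case_id": out_case, "examiner_id": out_exam})
    return design.sort_values(["case_id", "examiner_id"], ignore_index=True)


def _correctness_prob(
    latent: np.ndarray, difficulty: np.ndarray, ceiling: float, k: float
) -> np.ndarray:
    """P(correct call) under the ceiling-probit difficulty link.

    ``ceiling * Phi(theta - k * d)`` with the intercept ``theta`` chosen so
    that the expectation over d ~ N(0, 1) equals the latent operating point:
    E[Phi(a - k d)] = Phi(a / sqrt(1 + k^2)), hence
    theta = sqrt(1 + k^2) * Phi^{-1}(latent / ceiling).
    """
    theta = np.sqrt(1.0 + k**2) * stats.norm.ppf(latent / ceiling)
    return ceiling * stats.norm.cdf(theta - k * difficulty)


def simulate_assessments(
    cases: pd.DataFrame,
    examiners: pd.DataFrame,
    design: pd.DataFrame,
    config: CohortConfig,
    seed,
) -> pd.DataFrame:
    """Simulate one binary call + confidence rating per (case, examiner) pair.

    The probability of a correct call decreases with case difficulty and
    increases with the examiner's latent operating point; marginally over
    difficulty each examiner's sensitivity and specificity equal their
    latent values exactly.  Confidence is certain / probable / uncertain by
    thresholding the examiner's noisy perception of case difficulty.
    """
    rng = _rng_for(seed, "assessments")
    df = design.merge(
        cases[["case_id", "label", "difficulty"]], on="case_id", validate="m:1"
    ).merge(
        examiners[["examiner_id", "tier", "latent_sens", "latent_spec"]],
        on="examiner_id",
        validate="m:1",
    )
    label = df["label"].to_numpy()
    latent = np.where(label == 1, df["latent_sens"], df["latent_spec"])
    p_correct = _correctness_prob(
        latent, df["difficulty"].to_numpy(), config.examiner_ceiling,
        config.difficulty_weight,
    )
    correct = rng.random(len(df)) < p_correct
    call = np.where(correct, label, 1 - label)

    perceived = df["difficulty"].to_numpy() + rng.normal(
        0.0, config.confidence_noise_sd, size=len(df)
    )
    t1, t2 = config.confidence_thresholds
    confidence = np.where(
        perceived < t1, "certain", np.where(perceived < t2, "probable", "uncertain")
    )
    return pd.DataFrame(
        {
            "examiner_id": df["examiner_id"],
            "case_id": df["case_id"],
            "call": call,
            "confidence": confidence,
        }
    )


def _class_prior(config: CohortConfig) -> float:
    pm = sum(config.category_probs[c] for c in MALIGNANT_CODES)
    pm = pm / sum(config.category_probs.values())
    return (1.0 - config.conservative_fraction) * pm


def simulate_ai_predictions(
    cases: pd.DataFrame, config: CohortConfig, seed
) -> pd.DataFrame:
    """Simulate per-image 10-category probability vectors for every case.

    A case-level latent signal ``z | class ~ N(+-mu, 1)`` loads on the shared
    case difficulty (hard cases sit near the decision boundary for the AI as
    well as for examiners); each image observes ``z`` plus independent
    Gaussian noise.  The image-level malignant mass is the exact posterior
    P(malignant | z_image), so in "calibrated" mode predicted risks match
    observed malignancy frequencies by construction; "overconfident" /
    "underconfident" modes apply logit-scale temperature scaling.  The
    malignant mass is spread over the five malignant categories (and the
    benign mass over the five benign ones) by a Dirichlet draw concentrated
    on the case's true category.
    """
    config.validate()
    rng = _rng_for(seed, "ai_predictions")
    n = len(cases)
    mu = config.ai_separation
    a = config.ai_difficulty_loading
    if not 0.0 <= a < 1.0:
        raise ValueError("ai_difficulty_loading must be in [0, 1)")
    b = np.sqrt(1.0 - a * a)
    sign = np.where(cases["label"].to_numpy() == 1, 1.0, -1.0)
    z = sign * (mu - a * cases["difficulty"].to_numpy()) + b * rng.standard_normal(n)

    n_img = cases["n_images"].to_numpy(int)
    total = int(n_img.sum())
    case_rep = np.repeat(np.arange(n), n_img)
    z_img = z[case_rep] + config.ai_image_noise_sd * rng.standard_normal(total)

    pi = _class_prior(config)
    s2 = 1.0 + config.ai_image_noise_sd**2
    # posterior log-odds of malignancy for z_img | class ~ N(+-mu, s2)
    log_odds = 2.0 * mu * z_img / s2 + np.log(pi / (1.0 - pi))
    if config.ai_calibration == "overconfident":
        log_odds = config.ai_temperature * log_odds
    elif config.ai_calibration == "underconfident":
        log_odds = log_odds / config.ai_temperature
    s = expit(log_odds)

    # spread class mass over the five categories of each class
    conc = config.ai_category_concentration
    boost = config.ai_true_category_boost
    cat_idx = np.array(
        [CATEGORY_CODES.index(c) for c in cases["histology"]], int
    )[case_rep]
    alpha = np.full((total, 10), conc)
    alpha[np.arange(total), cat_idx] += boost
    g = rng.gamma(alpha)
    wb = g[:, :5] / g[:, :5].sum(axis=1, keepdims=True)
    wm = g[:, 5:] / g[:, 5:].sum(axis=1, keepdims=True)
    probs = np.hstack([wb * (1.0 - s)[:, None], wm * s[:, None]])

    out = pd.DataFrame(probs, columns=[f"p_{i + 1}" for i in range(10)])
    out.insert(0, "case_id", cases["case_id"].to_numpy()[case_rep])
    img_id = np.concatenate([np.arange(k) for k in n_img])
    out.insert(1, "image_id", img_id)
    return out


def generate_cohort(config: CohortConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Run all generator stages off named substreams of one master seed."""
    cases = generate_cases(config, seed)
    examiners = generate_examiner_panel(config, seed)
    design = assign_reviews(cases, examiners, config, seed)
    assessments = simulate_assessments(cases, examiners, design, config, seed)
    image_preds = simulate_ai_predictions(cases, config, seed)
    return {
        "cases": cases,
        "examiners": examiners,
        "design": design,
        "assessments": assessments,
        "image_preds": image_preds,
    }
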