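"""Configuration objects and seed management.

All randomness in the package flows from a single master seed through named
per-stage substreams (:func:`stage_rng`), so each pipeline stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

#: Stable substream indices per pipeline stage.  Appending a stage keeps the
#: streams of all existing stages unchanged.
_STAGE_IDS = {
    "cases": 0,
    "examiners": 1,
    "design": 2,
    "assessments": 3,
    "ai_predictions": 4,
    "bootstrap": 5,
    "triage": 6,
    "roc_band": 7,
    "pooled": 8,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A Generator for one named pipeline stage derived from the master seed."""
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGE_IDS)}")
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_IDS[stage]]))


# Test-data composition of the study cohort: 2,660 surgically verified cases,
# 1,575 benign / 1,085 malignant (40.8% malignant).  Rare-benign cases are
# folded into the "other common benign" category.
_DEFAULT_CATEGORY_PROBS = {
    "endometrioma": 276 / 2660,
    "dermoid": 340 / 2660,
    "other_common_benign": (222 + 50) / 2660,
    "solid_benign": 118 / 2660,
    "cystadenofibroma": 569 / 2660,
    "borderline_serous": 160 / 2660,
    "borderline_mucinous": 79 / 2660,
    "cancer_epithelial": 611 / 2660,
    "cancer_nonepithelial": 89 / 2660,
    "metastasis": 146 / 2660,
}

_DEFAULT_US_SYSTEM_PROBS = {
    "GE": 0.918,
    "Samsung": 0.048,
    "Philips": 0.014,
    "Mindray": 0.012,
    "Other": 0.008,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study conditions: 19 centers with 140 cases each
    (2,660 cases, 40.8% malignant), an image-count distribution with median 4
    (IQR 3-6), panels of 33 expert and 33 non-expert examiners whose tier
    operating points match the pooled single-examiner rows (expert
    82.40%/82.67% sensitivity/specificity, non-expert 78.71%/77.27%), review
    minimums of 7 experts and 6 non-experts per case with own-center
    exclusion, and a calibrated AI scorer.
    """

    # cohort composition
    n_centers: int = 19
    cases_per_center: int = 140
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_PROBS)
    )
    conservative_fraction: float = 0.0
    us_system_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_US_SYSTEM_PROBS)
    )
    exam_year_range: tuple[int, int] = (2006, 2021)
    # age model (years): benign and malignant lesions have different means
    age_mean_benign: float = 45.0
    age_mean_malignant: float = 58.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 90.0)

    # image-count model: n_images = 1 + NegBin(r, p) with mean `1 + nb_mean`,
    # parameterised so the quartiles of n_images are (3, 4, 6)
    image_count_r: float = 2.4
    image_count_mean: float = 3.85

    # examiner panel
    n_experts: int = 33
    n_nonexperts: int = 33
    expert_sens: float = 0.8240
    expert_spec: float = 0.8267
    nonexpert_sens: float = 0.7871
    nonexpert_spec: float = 0.7727
    #: between-examiner s.d. of logit sensitivity/specificity
    examiner_logit_sd: float = 0.40
    #: between-examiner correlation of logit sensitivity and logit specificity
    examiner_logit_corr: float = -0.3
    #: accuracy on the easiest possible case (limit of the difficulty link)
    examiner_ceiling: float = 0.99
    #: weight of latent case difficulty in the correctness link
    difficulty_weight: float = 1.0
    #: confidence thresholds on perceived difficulty and perception noise s.d.
    confidence_thresholds: tuple[float, float] = (0.3, 1.2)
    confidence_noise_sd: float = 0.5
    #: lognormal s.d. of per-examiner review propensity (workload variation)
    propensity_sd: float = 0.5

    # review design
    min_experts_per_case: int = 7
    min_nonexperts_per_case: int = 6
    experts_per_case_mean: float = 10.0
    nonexperts_per_case_mean: float = 9.0
    panel_size_sd: float = 1.5
    experts_per_case_max: int = 13
    nonexperts_per_case_max: int = 12

    # AI model: latent signal z | class ~ N(+-ai_separation, 1), with the
    # case's difficulty loading on z; image scores are exact posteriors of
    # z_image | class, so "calibrated" mode is calibrated by construction
    ai_separation: float = 1.2
    ai_difficulty_loading: float = 0.6
    ai_image_noise_sd: float = 0.3
    ai_calibration: str = "calibrated"  # calibrated | overconfident | underconfident
    #: logit-scale temperature applied in the two miscalibrated modes
    ai_temperature: float = 2.0
    #: Dirichlet concentration for spreading class mass over the 5 categories
    ai_category_concentration: float = 0.5
    #: extra concentration on the case's true category
    ai_true_category_boost: float = 8.0

    def validate(self) -> None:
        if self.n_centers <= 0 or self.cases_per_center <= 0:
            raise ValueError("n_centers and cases_per_center must be positive")
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"category_probs sum to {total}, expected 1")
        if any(p < 0 for p in self.category_probs.values()):
            raise ValueError("category_probs must be non-negative")
        if not 0.0 <= self.conservative_fraction < 1.0:
            raise ValueError("conservative_fraction must be in [0, 1)")
        if self.n_experts <= 0 or self.n_nonexperts <= 0:
            raise ValueError("examiner counts must be positive")
        for p in (self.expert_sens, self.expert_spec, self.nonexpert_sens,
                  self.nonexpert_spec):
            if not 0.0 < p < 1.0:
                raise ValueError("tier operating points must be in (0, 1)")
        if not 0.0 < self.examiner_ceiling <= 1.0:
            raise ValueError("examiner_ceiling must be in (0, 1]")
        if max(self.expert_sens, self.expert_spec, self.nonexpert_sens,
               self.nonexpert_spec) > self.examiner_ceiling:
            raise ValueError("tier operating points must not exceed the ceiling")
        if abs(self.examiner_logit_corr) > 1:
            raise ValueError("examiner_logit_corr must be in [-1, 1]")
        if self.ai_calibration not in ("calibrated", "overconfident", "underconfident"):
            raise ValueError(f"unknown calibration mode {self.ai_calibration!r}")
        t1, t2 = self.confidence_thresholds
        if not t1 < t2:
            raise ValueError("confidence thresholds must be increasing")

    @property
    def n_cases(self) -> int:
        return self.n_centers * self.cases_per_center

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CohortConfig":
        kwargs = dict(d)
        for key in ("exam_year_range", "age_range", "confidence_thresholds"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class AnalysisConfig:
    """Knobs of the evaluation, comparison and triage stages."""

    cutoff: float = 0.5
    n_boot: int = 2000
    n_reps: int = 1000
    calibration_bins: int = 10
    roc_grid_points: int = 1001
    ci_level: float = 0.95
    pooled_metric: str = "f1"
    subgroup_columns: tuple[str, ...] = (
        "center_id", "us_system", "histology", "age_group", "exam_year",
    )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        kwargs = dict(d)
        if "subgroup_columns" in kwargs:
            kwargs["subgroup_columns"] = tuple(kwargs["subgroup_columns"])
        return cls(**kwargs)


@dataclass
class RunConfig:
    """Full pipeline run configuration: paths, cohort block, analysis block, seed."""

    outdir: Path = Path("ovatriage_run")
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    verbosity: str = "info"

    # table paths, relative to outdir unless absolute
    cases_path: str = "cases.csv"
    examiners_path: str = "examiners.csv"
    design_path: str = "design.csv"
    assessments_path: str = "assessments.csv"
    image_preds_path: str = "image_preds.csv"
    case_scores_path: str = "case_scores.csv"
    metrics_path: str = "metrics.json"
    subgroup_metrics_path: str = "subgroup_metrics.csv"
    paired_scores_path: str = "paired_scores.csv"
    roc_curve_path: str = "roc_curve.csv"
    roc_band_path: str = "roc_band.csv"
    bivariate_path: str = "bivariate_summary.json"
    calibration_path: str = "calibration.csv"
    comparison_report_path: str = "comparison_report.json"
    triage_results_path: str = "triage_results.json"
    triage_decisions_path: str = "triage_decisions.csv"
    run_report_path: str = "run_report.json"

    def path(self, name: str) -> Path:
        p = Path(getattr(self, f"{name}_path"))
        return p if p.is_absolute() else Path(self.outdir) / p

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], **overrides: Any) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        for key, value in raw.items():
            if key == "cohort":
                kwargs["cohort"] = CohortConfig.from_dict(value)
            elif key == "analysis":
                kwargs["analysis"] = AnalysisConfig.from_dict(value)
            elif key == "outdir":
                kwargs["outdir"] = Path(value)
            else:
                kwargs[key] = value
        if "seed" not in kwargs:
            raise ValueError("a seed is mandatory for any stochastic stage")
        cfg = cls(**kwargs)
        cfg.cohort.validate()
        return cfg
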