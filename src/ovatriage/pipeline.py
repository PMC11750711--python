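"""Pipeline orchestration: simulate -> score -> evaluate -> compare ->
triage -> report, with input validation, per-stage seeding and a run report.

Every stage reads and writes the plain-CSV/JSON artifacts named in the run
configuration; stages are skipped when their outputs already exist unless
forced.  CSV dialect is fixed: UTF-8, header row, "." decimal separator.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_cohort
from .comparison import (
    bivariate_summary,
    calibration_curve,
    paired_scores,
    pooled_examiner_metrics,
    roc_confidence_band,
    roc_curve,
    wilcoxon_signed_rank,
)
from .config import RunConfig, stage_rng
from .metrics import auc, brier, confusion, grouped_metrics, metric_set
from .scoring import score_cases
from .triage import TriageStrategy, simulate_triage

__all__ = ["ValidationReport", "RunReport", "validate_inputs", "run_pipeline", "STAGES"]

STAGES = ("simulate", "score", "evaluate", "compare", "triage", "report")

_CASE_COLS = ["case_id", "center_id", "histology", "label", "age", "exam_year",
              "us_system", "management", "n_images"]
_DEFAULT_STRATEGIES = (
    "single_nonexpert", "single_expert", "current_practice", "ai_alone",
    "ai_assisted_nonexpert", "ai_assisted_expert",
)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    cases: pd.DataFrame,
    assessments: Optional[pd.DataFrame] = None,
    image_preds: Optional[pd.DataFrame] = None,
    design: Optional[pd.DataFrame] = None,
    prob_tol: float = 1e-6,
) -> ValidationReport:
    """Schema, referential-integrity and invariant checks on input tables.

    Hard errors (schema violations, orphan case ids, probability rows off by
    more than the tolerance, conservative cases labelled malignant) are
    distinguished from warnings (e.g. duplicated assessments).
    """
    rep = ValidationReport()
    missing = [c for c in _CASE_COLS if c not in cases.columns]
    if missing:
        rep.errors.append(f"cases table lacks columns {missing}")
        return rep
    if cases["case_id"].duplicated().any():
        rep.errors.append("duplicate case_id in cases table")
    if (cases["n_images"] < 1).any():
        rep.errors.append("cases with n_images < 1")
    bad = cases[(cases["management"] == "conservative") & (cases["label"] == 1)]
    if len(bad):
        rep.errors.append(
            f"{len(bad)} conservatively managed cases labelled malignant"
        )
    known = set(cases["case_id"])

    if assessments is not None:
        orphan = set(assessments["case_id"]) - known
        if orphan:
            rep.errors.append(
                f"assessments reference unknown cases {sorted(orphan)[:5]}"
            )
        dup = assessments.duplicated(["examiner_id", "case_id"])
        if dup.any():
            rep.errors.append(f"{int(dup.sum())} duplicated (examiner, case) assessments")
        if design is not None:
            pairs = set(map(tuple, design[["case_id", "examiner_id"]].to_numpy()))
            extra = [
                t for t in map(tuple, assessments[["case_id", "examiner_id"]].to_numpy())
                if t not in pairs
            ]
            if extra:
                rep.errors.append(
                    f"{len(extra)} assessments outside the review design"
                )
    if image_preds is not None:
        orphan = set(image_preds["case_id"]) - known
        if orphan:
            rep.errors.append(
                f"image predictions reference unknown cases {sorted(orphan)[:5]}"
            )
        pcols = [f"p_{i + 1}" for i in range(10)]
        missing = [c for c in pcols if c not in image_preds.columns]
        if missing:
            rep.errors.append(f"image_preds lacks columns {missing}")
        else:
            probs = image_preds[pcols].to_numpy(float)
            sums = probs.sum(axis=1)
            bad_rows = np.flatnonzero(
                (np.abs(sums - 1.0) > prob_tol) | (probs < -prob_tol).any(axis=1)
            )
            for i in bad_rows[:5]:
                rep.errors.append(
                    f"image_preds row {i} (case "
                    f"{image_preds['case_id'].iat[int(i)]}) sums to {sums[i]:.6f}"
                )
            if len(bad_rows) > 5:
                rep.errors.append(f"... {len(bad_rows) - 5} more invalid probability rows")
    return rep


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            return None
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    return obj


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2)


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


@dataclass
class RunReport:
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, elapsed: float, skipped: bool, **info) -> None:
        self.stages[stage] = {"seconds": round(elapsed, 3), "skipped": skipped, **info}

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _outputs_current(paths: Iterable[Path]) -> bool:
    return all(p.exists() for p in paths)


def _stage_simulate(cfg: RunConfig) -> dict:
    cohort = generate_cohort(cfg.cohort, cfg.seed)
    _write_csv(cfg.path("cases"), cohort["cases"][_CASE_COLS])
    _write_csv(cfg.path("examiners"), cohort["examiners"])
    _write_csv(cfg.path("design"), cohort["design"])
    _write_csv(cfg.path("assessments"), cohort["assessments"])
    _write_csv(cfg.path("image_preds"), cohort["image_preds"])
    return {"n_cases": len(cohort["cases"]),
            "n_assessments": len(cohort["assessments"]),
            "n_images": len(cohort["image_preds"])}


def _stage_score(cfg: RunConfig) -> dict:
    preds = pd.read_csv(cfg.path("image_preds"))
    scores = score_cases(preds, cutoff=cfg.analysis.cutoff)
    _write_csv(cfg.path("case_scores"), scores)
    return {"n_cases": len(scores), "cutoff": cfg.analysis.cutoff}


def _age_group(age: pd.Series) -> pd.Series:
    return pd.cut(
        age, [0, 30, 40, 50, 60, 70, 200],
        labels=["<30", "30-39", "40-49", "50-59", "60-69", "70+"],
    ).astype(str)


def _stage_evaluate(cfg: RunConfig) -> dict:
    cases = pd.read_csv(cfg.path("cases"))
    scores = pd.read_csv(cfg.path("case_scores"))
    df = cases.merge(scores, on="case_id", validate="1:1")
    surg = df[df["management"] == "surgery"]
    cm = confusion(surg["prediction"], surg["label"])
    ms = metric_set(cm)
    ms.brier = brier(surg["malignancy_score"], surg["label"])
    ms.auc = auc(surg["malignancy_score"], surg["label"])
    out = {
        "ai_models": {
            "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
            "metrics": ms.to_dict(),
            "metrics_percent": ms.to_percent_dict(),
        },
        "n_cases": len(surg),
    }
    cons = df[df["management"] == "conservative"]
    if len(cons):
        # specificity among conservatively managed (all-benign) cases
        from .metrics import jeffreys_ci

        k = int((cons["prediction"] == 0).sum())
        n = len(cons)
        lo, hi = jeffreys_ci(k, n)
        out["conservative"] = {
            "n": n, "correct": k, "specificity": k / n,
            "jeffreys_ci": [lo, hi],
        }
    _write_json(cfg.path("metrics"), out)

    sub = surg.copy()
    sub["age_group"] = _age_group(sub["age"])
    frames = []
    for col in cfg.analysis.subgroup_columns:
        if col not in sub.columns:
            continue
        g = grouped_metrics(sub["prediction"], sub["label"], sub[col])
        g.insert(0, "subgroup_by", col)
        frames.append(g)
    _write_csv(cfg.path("subgroup_metrics"), pd.concat(frames, ignore_index=True))
    return {"n_surgical": len(surg), "n_conservative": len(cons)}


def _stage_compare(cfg: RunConfig) -> dict:
    cases = pd.read_csv(cfg.path("cases"))
    scores = pd.read_csv(cfg.path("case_scores"))
    assessments = pd.read_csv(cfg.path("assessments"))
    examiners = pd.read_csv(cfg.path("examiners"))
    surg = cases[cases["management"] == "surgery"]
    assessments = assessments[assessments["case_id"].isin(set(surg["case_id"]))]

    pairs = paired_scores(assessments, scores, surg,
                          metric=cfg.analysis.pooled_metric, examiners=examiners)
    _write_csv(cfg.path("paired_scores"), pairs)

    report: dict = {"metric": cfg.analysis.pooled_metric}
    for tier in ("expert", "non-expert"):
        sub = pairs[pairs["tier"] == tier].dropna(
            subset=["examiner_metric", "ai_metric"]
        )
        stat, p = wilcoxon_signed_rank(
            (sub["ai_metric"] - sub["examiner_metric"]).to_numpy()
        )
        pooled = pooled_examiner_metrics(
            assessments, surg, tier, examiners,
            n_reps=cfg.analysis.n_boot, seed=stage_rng(cfg.seed, "pooled"),
        )
        counts = _per_examiner_counts(assessments, surg, tier, examiners)
        biv = bivariate_summary(counts)
        report[tier] = {
            "n_examiners": len(sub),
            "wilcoxon": {"statistic": stat, "p": p},
            "pooled": pooled.to_dict(orient="index"),
            "bivariate": biv.to_dict(),
        }

    merged = surg.merge(scores, on="case_id", validate="1:1")
    s, y = merged["malignancy_score"].to_numpy(), merged["label"].to_numpy()
    curve = roc_curve(s, y)
    _write_csv(cfg.path("roc_curve"), curve)
    band = roc_confidence_band(
        s, y, n_boot=max(200, cfg.analysis.n_boot // 4),
        grid=cfg.analysis.roc_grid_points, seed=stage_rng(cfg.seed, "roc_band"),
    )
    _write_csv(cfg.path("roc_band"), band.to_frame())
    cal, mace = calibration_curve(s, y, n_bins=cfg.analysis.calibration_bins)
    _write_csv(cfg.path("calibration"), cal)
    report["ai"] = {"auc": auc(s, y), "brier": brier(s, y),
                    "calibration_mace": mace}
    _write_json(cfg.path("bivariate"), {
        t: report[t]["bivariate"] for t in ("expert", "non-expert")
    })
    _write_json(cfg.path("comparison_report"), report)
    return {"wilcoxon_p_expert": report["expert"]["wilcoxon"]["p"],
            "wilcoxon_p_nonexpert": report["non-expert"]["wilcoxon"]["p"]}


def _per_examiner_counts(assessments, cases, tier, examiners) -> pd.DataFrame:
    ids = examiners.loc[examiners["tier"] == tier, "examiner_id"]
    df = assessments[assessments["examiner_id"].isin(set(ids))].merge(
        cases[["case_id", "label"]], on="case_id"
    )
    g = df.groupby("examiner_id")
    out = pd.DataFrame({
        "tp": g.apply(lambda x: int(((x["call"] == 1) & (x["label"] == 1)).sum()),
                      include_groups=False),
        "fn": g.apply(lambda x: int(((x["call"] == 0) & (x["label"] == 1)).sum()),
                      include_groups=False),
        "tn": g.apply(lambda x: int(((x["call"] == 0) & (x["label"] == 0)).sum()),
                      include_groups=False),
        "fp": g.apply(lambda x: int(((x["call"] == 1) & (x["label"] == 0)).sum()),
                      include_groups=False),
    }).reset_index()
    return out


def _stage_triage(cfg: RunConfig) -> dict:
    cases = pd.read_csv(cfg.path("cases"))
    scores = pd.read_csv(cfg.path("case_scores"))
    assessments = pd.read_csv(cfg.path("assessments"))
    examiners = pd.read_csv(cfg.path("examiners"))
    surg = cases[cases["management"] == "surgery"].reset_index(drop=True)
    rng = stage_rng(cfg.seed, "triage")
    results = {}
    decisions = []
    for name in _DEFAULT_STRATEGIES:
        res = simulate_triage(
            surg, assessments, examiners, scores,
            TriageStrategy(name, cutoff=cfg.analysis.cutoff),
            n_reps=cfg.analysis.n_reps, seed=rng,
        )
        res.seed = cfg.seed
        results[name] = res.to_dict()
        d = res.decisions.copy()
        d.insert(0, "strategy", name)
        decisions.append(d)
    _write_json(cfg.path("triage_results"), results)
    _write_csv(cfg.path("triage_decisions"), pd.concat(decisions, ignore_index=True))
    return {
        name: {"human_resources": results[name]["human_resources"]["estimate"]}
        for name in results
    }


def _stage_report(cfg: RunConfig) -> dict:
    from . import plots

    out = {}
    try:
        band = pd.read_csv(cfg.path("roc_band"))
        cal = pd.read_csv(cfg.path("calibration"))
        figdir = Path(cfg.outdir) / "figures"
        out["roc_figure"] = str(plots.plot_roc_band(band, figdir / "roc_band.png"))
        out["calibration_figure"] = str(
            plots.plot_calibration(cal, figdir / "calibration.png")
        )
    except FileNotFoundError:
        out["figures"] = "skipped (comparison outputs missing)"
    return out


_STAGE_FUNCS = {
    "simulate": (_stage_simulate,
                 ("cases", "examiners", "design", "assessments", "image_preds")),
    "score": (_stage_score, ("case_scores",)),
    "evaluate": (_stage_evaluate, ("metrics", "subgroup_metrics")),
    "compare": (_stage_compare,
                ("paired_scores", "roc_curve", "roc_band", "bivariate",
                 "calibration", "comparison_report")),
    "triage": (_stage_triage, ("triage_results", "triage_decisions")),
    "report": (_stage_report, ()),
}


def run_pipeline(
    cfg: RunConfig,
    stages: Iterable[str] = STAGES,
    force: bool = False,
    log=None,
) -> RunReport:
    """Execute the requested stages in dependency order.

    A stage whose outputs all exist is skipped unless ``force``.  Any stage
    failure aborts with a stage-attributed message.  Returns the run report
    (also written to ``run_report.json``).
    """
    report = RunReport(seed=cfg.seed)
    order = [s for s in STAGES if s in set(stages)]
    # validate before executing when running on existing tables
    if "simulate" not in order and cfg.path("cases").exists():
        tables = {"cases": pd.read_csv(cfg.path("cases"))}
        for name in ("assessments", "image_preds", "design"):
            p = cfg.path(name)
            if p.exists():
                tables[name] = pd.read_csv(p)
        val = validate_inputs(**tables)
        if not val.ok:
            raise ValueError("input validation failed: " + "; ".join(val.errors))
        report.warnings.extend(val.warnings)
    for stage in order:
        fn, outputs = _STAGE_FUNCS[stage]
        paths = [cfg.path(name) for name in outputs]
        t0 = time.perf_counter()
        if outputs and not force and _outputs_current(paths):
            report.record(stage, 0.0, skipped=True)
            if log:
                log(f"{stage}: outputs current, skipped")
            continue
        try:
            info = fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report.record(stage, time.perf_counter() - t0, skipped=False, **(info or {}))
        if log:
            log(f"{stage}: done in {report.stages[stage]['seconds']}s")
    _write_json(cfg.path("run_report"), report.to_dict())
    return report
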