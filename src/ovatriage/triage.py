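"""Second-reader triage workflow simulation.

Simulates management-decision workflows over a reviewed cohort and reports
diagnostic performance together with human-resource demands (the expected
number of human examinations needed per management decision; the AI is not
counted as a human resource, so every workflow costs at least the one
acquiring examination).

Workflows:

- ``current_practice`` — a non-expert assesses first; cases with an
  uncertain diagnosis or a presumed malignancy are referred to an expert,
  whose call is final.
- ``ai_assisted_nonexpert`` / ``ai_assisted_expert`` — the AI and the
  initial (non-)expert each assess; on agreement their shared call is final
  after one examination, on disagreement a (second) expert arbitrates.
- ``single_expert`` / ``single_nonexpert`` — one examiner, no referral.
- ``ai_alone`` — the AI call at the configured cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd

from .comparison import (
    _sample_one_per_case,
    _vectorised_metric_suite,
    examiner_sampling_weights,
    summarise_replicates,
)

__all__ = [
    "STRATEGIES",
    "TriageStrategy",
    "TriageDecision",
    "TriageResult",
    "decide_current_practice",
    "decide_ai_assisted",
    "simulate_triage",
    "referral_reduction",
]

STRATEGIES = (
    "current_practice",
    "ai_assisted_nonexpert",
    "ai_assisted_expert",
    "single_expert",
    "single_nonexpert",
    "ai_alone",
    # variant: expert-initial current practice, not part of the default report
    "current_practice_expert",
)


@dataclass(frozen=True)
class TriageStrategy:
    name: str
    cutoff: float = 0.5

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; known: {STRATEGIES}")


@dataclass(frozen=True)
class TriageDecision:
    case_id: Any
    final_call: int
    examinations: int
    referred: bool

    def __post_init__(self):
        if self.referred != (self.examinations == 2):
            raise ValueError("referred must hold exactly when examinations == 2")


def _call_of(a) -> int:
    return int(a["call"] if isinstance(a, dict) else a.call)


def _confidence_of(a) -> str:
    return str(a["confidence"] if isinstance(a, dict) else a.confidence)


def _case_of(a):
    return a["case_id"] if isinstance(a, dict) else a.case_id


def decide_current_practice(initial, expert=None) -> TriageDecision:
    """Current-practice rule: refer to an expert when the initial non-expert
    is uncertain or presumes malignancy; the expert's call is then final."""
    refer = _confidence_of(initial) == "uncertain" or _call_of(initial) == 1
    if refer:
        if expert is None:
            raise ValueError("referred case lacks an expert assessment")
        return TriageDecision(_case_of(initial), _call_of(expert), 2, True)
    return TriageDecision(_case_of(initial), _call_of(initial), 1, False)


def decide_ai_assisted(ai_call: int, initial, arbiter=None) -> TriageDecision:
    """AI second-reader rule: on AI/examiner agreement the shared call is
    final after one examination; on disagreement an expert arbitrates."""
    ai_call = int(ai_call)
    if ai_call == _call_of(initial):
        return TriageDecision(_case_of(initial), ai_call, 1, False)
    if arbiter is None:
        raise ValueError("disagreement but no arbiter assessment available")
    return TriageDecision(_case_of(initial), _call_of(arbiter), 2, True)


def referral_reduction(hr_baseline: float, hr_new: float) -> float:
    """Percentage reduction in referrals implied by two human-resource
    figures, via the identity HR = 1 + referral fraction."""
    if hr_baseline <= 1.0:
        raise ValueError("baseline workflow has no referrals to reduce")
    if hr_new < 1.0:
        raise ValueError("human resources cannot fall below 1")
    return 100.0 * (1.0 - (hr_new - 1.0) / (hr_baseline - 1.0))


@dataclass
class TriageResult:
    strategy: TriageStrategy
    metrics: pd.DataFrame              # index: metric; estimate, ci_lo, ci_hi
    human_resources: tuple[float, float, float]
    referral_fraction: float
    n_reps: int
    seed: Optional[int] = None
    decisions: Optional[pd.DataFrame] = None  # per-case decisions, replicate 0

    def to_dict(self) -> dict:
        hr, lo, hi = self.human_resources
        return {
            "strategy": self.strategy.name,
            "cutoff": self.strategy.cutoff,
            "metrics": {
                m: {k: (None if not np.isfinite(v) else float(v))
                    for k, v in row.items()}
                for m, row in self.metrics.to_dict(orient="index").items()
            },
            "human_resources": {"estimate": hr, "ci_lo": lo, "ci_hi": hi},
            "referral_fraction": self.referral_fraction,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


class _TierDraws:
    """Pre-sorted per-tier assessment table with inverse-workload weights,
    supporting vectorised one-examiner-per-case draws."""

    def __init__(self, assessments: pd.DataFrame, examiners: pd.DataFrame,
                 tier: str, case_order: np.ndarray):
        ids = set(examiners.loc[examiners["tier"] == tier, "examiner_id"])
        sub = assessments[assessments["examiner_id"].isin(ids)]
        have = set(sub["case_id"])
        missing = [c for c in case_order if c not in have]
        if missing:
            raise ValueError(
                f"cases {missing[:5]} lack any {tier} assessment"
            )
        workloads = sub["examiner_id"].value_counts()
        w = examiner_sampling_weights(sub[["case_id", "examiner_id"]], workloads)
        sub = sub.merge(w, on=["case_id", "examiner_id"])
        pos = {c: i for i, c in enumerate(case_order)}
        sub = sub[sub["case_id"].isin(pos)].copy()
        sub["__code"] = sub["case_id"].map(pos)
        # renormalise within the retained cases
        sub["weight"] = sub["weight"] / sub.groupby("__code")["weight"].transform("sum")
        sub = sub.sort_values("__code", kind="stable").reset_index(drop=True)
        self.codes = sub["__code"].to_numpy()
        self.weights = sub["weight"].to_numpy()
        self.calls = sub["call"].to_numpy(int)
        self.confidence = sub["confidence"].to_numpy(object)
        self.examiner = sub["examiner_id"].to_numpy(object)
        self.n_cases = len(case_order)
        self.per_case_count = np.bincount(self.codes, minlength=self.n_cases)

    def draw(self, n_reps: int, rng: np.random.Generator) -> np.ndarray:
        return _sample_one_per_case(
            self.codes, self.weights, self.n_cases, n_reps, rng
        )

    def redraw_excluding(self, idx: np.ndarray, exclude_rows: np.ndarray,
                         need: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Replace draws equal to ``exclude_rows`` where ``need`` holds, by
        rejection; equivalent to sampling with the excluded examiner's
        weight removed."""
        clash = need & (idx == exclude_rows)
        if (clash & (self.per_case_count[None, :] < 2)).any():
            raise ValueError("a referred case has no eligible distinct arbiter")
        while clash.any():
            reps, cs = np.nonzero(clash)
            fresh = self.draw(1, rng)[0]
            idx[reps, cs] = fresh[cs]
            clash = need & (idx == exclude_rows)
        return idx


def simulate_triage(
    cases: pd.DataFrame,
    assessments: pd.DataFrame,
    examiners: pd.DataFrame,
    ai_predictions: Optional[pd.DataFrame],
    strategy: TriageStrategy | str,
    n_reps: int = 1000,
    seed=0,
    level: float = 0.95,
) -> TriageResult:
    """Monte-Carlo simulation of one triage workflow over the cohort.

    Per replicate, the initial examiner (and, for referred cases, the
    arbitration expert, drawn among that case's experts and excluding the
    initial examiner where both are experts) is drawn per case with
    inverse-workload weights; the metric suite and the human-resource figure
    are averaged over replicates with percentile CIs.

    ``ai_predictions`` must hold case_id and ``prediction`` (the binary AI
    call at the strategy's cutoff) for the AI arms; it may be None otherwise.
    """
    if isinstance(strategy, str):
        strategy = TriageStrategy(strategy)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_order = cases["case_id"].to_numpy()
    labels = cases["label"].to_numpy(int)
    n_cases = len(case_order)
    name = strategy.name

    needs_ai = name in ("ai_assisted_nonexpert", "ai_assisted_expert", "ai_alone")
    if needs_ai:
        if ai_predictions is None:
            raise ValueError(f"strategy {name!r} needs AI predictions")
        ai_map = ai_predictions.set_index("case_id")["prediction"]
        if not set(case_order) <= set(ai_map.index):
            raise ValueError("AI predictions missing for some cases")
        ai_call = ai_map.reindex(case_order).to_numpy(int)

    if name == "ai_alone":
        final = np.tile(ai_call, (1, 1))
        referred = np.zeros((1, n_cases), bool)
        n_reps_eff = 1
        initial_exam = np.full(n_cases, "AI", object)
        arb_exam = np.full(n_cases, None, object)
    else:
        initial_tier = ("expert"
                        if name in ("single_expert", "ai_assisted_expert",
                                    "current_practice_expert")
                        else "non-expert")
        init = _TierDraws(assessments, examiners, initial_tier, case_order)
        idx0 = init.draw(n_reps, rng)
        calls0 = init.calls[idx0]
        n_reps_eff = n_reps

        if name in ("single_expert", "single_nonexpert"):
            final = calls0
            referred = np.zeros_like(calls0, bool)
            arb_idx = None
        else:
            experts = (init if initial_tier == "expert"
                       else _TierDraws(assessments, examiners, "expert", case_order))
            if name in ("current_practice", "current_practice_expert"):
                conf0 = init.confidence[idx0]
                referred = (conf0 == "uncertain") | (calls0 == 1)
            else:  # AI-assisted arms
                referred = calls0 != ai_call[None, :]
            arb_idx = experts.draw(n_reps, rng)
            if initial_tier == "expert":
                # the arbiter must be a second, distinct expert
                arb_idx = experts.redraw_excluding(arb_idx, idx0, referred, rng)
            final = np.where(referred, experts.calls[arb_idx], calls0)
        initial_exam = init.examiner[idx0[0]]
        arb_exam = np.full(n_cases, None, object)
        if name not in ("single_expert", "single_nonexpert"):
            arb_exam = np.where(
                referred[0], experts.examiner[arb_idx[0]], None
            )

    lab = np.broadcast_to(labels, final.shape)
    tp = ((final == 1) & (lab == 1)).sum(axis=1).astype(float)
    fp = ((final == 1) & (lab == 0)).sum(axis=1).astype(float)
    tn = ((final == 0) & (lab == 0)).sum(axis=1).astype(float)
    fn = ((final == 0) & (lab == 1)).sum(axis=1).astype(float)
    suite = _vectorised_metric_suite(tp, fp, tn, fn)
    hr_reps = 1.0 + referred.mean(axis=1)

    alpha = (1.0 - level) / 2.0
    metrics = summarise_replicates(suite, level=level)
    hr = (
        float(hr_reps.mean()),
        float(np.percentile(hr_reps, 100 * alpha)),
        float(np.percentile(hr_reps, 100 * (1 - alpha))),
    )
    decisions = pd.DataFrame(
        {
            "case_id": case_order,
            "label": labels,
            "final_call": final[0],
            "examinations": np.where(referred[0], 2, 1),
            "referred": referred[0],
            "initial_examiner": initial_exam,
            "arbiter": arb_exam,
        }
    )
    return TriageResult(
        strategy=strategy,
        metrics=metrics,
        human_resources=hr,
        referral_fraction=float(referred.mean()),
        n_reps=n_reps_eff,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        decisions=decisions,
    )
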