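"""What-if risk-control scenarios and control-priority ranking.

A control scenario models a targeted intervention on one indicator: its
occurrence-probability bounds ``p_min``/``p_max`` each drop by one level,
floored at level 1 (a bound already at the lowest level does not move). Loss
levels stay put by default — short-term interventions change how likely a risk
is, not how much damage it would do — though a loss-side decrement is available
behind an explicit flag.

Each scenario rebuilds memberships, the STM and its stationary distribution,
and is scored by the *safety score* ``P(S1) + P(S2)``: the long-run probability
of sitting in one of the two safe states. A control is *effective* when its
safety score strictly exceeds the uncontrolled baseline's. Ranking scenarios by
safety score yields the control-priority order for the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from ._rounding import round_half_up
from .errors import InputDomainError
from .markov import StateDistribution, steady_state
from .membership import IndicatorAssessment, StageAssessment
from .riskmatrix import RiskMatrixSpec
from .transition import build_stm

__all__ = [
    "ControlScenarioResult",
    "apply_control",
    "safety_score",
    "evaluate_scenario",
    "rank_controls",
    "scenario_table",
    "control_stage",
]

BASELINE_ID = "none"


@dataclass(frozen=True)
class ControlScenarioResult:
    """Stable state and safety score of one control scenario (or the baseline)."""

    stage_id: str
    controlled_indicator: str  # indicator id, or "none" for the baseline
    stable_state: StateDistribution
    safety_score: float
    baseline_score: float
    effective: bool
    rank: int | None = None  # 1-based among indicator scenarios; None for baseline

    @property
    def is_baseline(self) -> bool:
        return self.controlled_indicator == BASELINE_ID


def apply_control(
    a: IndicatorAssessment, levels: int = 1, decrement_loss: bool = False
) -> IndicatorAssessment:
    """Decrement the probability bounds by ``levels``, floored at level 1.

    Idempotent at the floor: an assessment already at ``p_min = p_max = 1`` is
    returned unchanged. Loss bounds are only touched when ``decrement_loss``
    is set.
    """
    if levels < 0:
        raise InputDomainError(f"control decrement must be >= 0, got {levels}")
    new = {
        "p_min": max(1, a.p_min - levels),
        "p_max": max(1, a.p_max - levels),
    }
    if decrement_loss:
        new["l_min"] = max(1, a.l_min - levels)
        new["l_max"] = max(1, a.l_max - levels)
    return replace(a, **new)


def safety_score(dist: StateDistribution, n_safe: int = 2) -> float:
    """Total stationary probability of the ``n_safe`` least dangerous states."""
    if not 1 <= n_safe <= dist.n_states:
        raise InputDomainError(
            f"n_safe must be in 1..{dist.n_states}, got {n_safe}"
        )
    return float(sum(dist.probs[:n_safe]))


def control_stage(
    stage: StageAssessment,
    controlled_ids: Sequence[str],
    levels: int = 1,
    decrement_loss: bool = False,
) -> StageAssessment:
    """The stage with controls applied to every id in ``controlled_ids``.

    Controlling several indicators at once generalizes the single-indicator
    scenarios; an empty sequence returns the stage unchanged.
    """
    out = stage
    for cid in controlled_ids:
        out = out.replace(apply_control(out.get(cid), levels, decrement_loss))
    return out


def evaluate_scenario(
    stage: StageAssessment,
    controlled: str | None,
    matrix: RiskMatrixSpec,
    *,
    levels: int = 1,
    decrement_loss: bool = False,
    policy: str = "identity",
    tol: float = 1e-12,
    max_iter: int = 10**6,
    _baseline_score: float | None = None,
) -> ControlScenarioResult:
    """Stable state and safety score after controlling one indicator.

    ``controlled=None`` (or ``"none"``) evaluates the unmodified baseline.
    The baseline's own score is recomputed unless supplied, so a lone call is
    self-contained.
    """
    if controlled in (None, BASELINE_ID):
        scenario, label = stage, BASELINE_ID
    else:
        scenario = control_stage(stage, [controlled], levels, decrement_loss)
        label = controlled

    result = steady_state(
        build_stm(scenario, matrix, policy=policy), tol=tol, max_iter=max_iter
    )
    score = safety_score(result.distribution)

    if label == BASELINE_ID:
        baseline = score
    elif _baseline_score is not None:
        baseline = _baseline_score
    else:
        base = steady_state(
            build_stm(stage, matrix, policy=policy), tol=tol, max_iter=max_iter
        )
        baseline = safety_score(base.distribution)

    return ControlScenarioResult(
        stage_id=stage.stage_id,
        controlled_indicator=label,
        stable_state=result.distribution,
        safety_score=score,
        baseline_score=baseline,
        effective=(label != BASELINE_ID and score > baseline),
    )


def rank_controls(
    stage: StageAssessment,
    matrix: RiskMatrixSpec,
    *,
    levels: int = 1,
    decrement_loss: bool = False,
    policy: str = "identity",
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> list[ControlScenarioResult]:
    """One scenario per indicator plus the baseline, best safety score first.

    Indicator scenarios carry ranks 1..n (descending safety score, ties broken
    by input order); the baseline is slotted into the sorted output with
    ``rank=None``.
    """
    kw = dict(
        levels=levels,
        decrement_loss=decrement_loss,
        policy=policy,
        tol=tol,
        max_iter=max_iter,
    )
    baseline = evaluate_scenario(stage, None, matrix, **kw)
    scenarios = [
        evaluate_scenario(
            stage, a.indicator_id, matrix,
            _baseline_score=baseline.safety_score, **kw
        )
        for a in stage
    ]
    order = sorted(range(len(scenarios)), key=lambda i: -scenarios[i].safety_score)
    ranked = [
        replace(scenarios[i], rank=pos) for pos, i in enumerate(order, start=1)
    ]
    everything = ranked + [baseline]
    everything.sort(
        key=lambda r: (-r.safety_score, r.rank if r.rank is not None else 0)
    )
    return everything


def scenario_table(
    results: Sequence[ControlScenarioResult], decimals: int = 3
) -> pd.DataFrame:
    """Report table: one row per scenario, probabilities rounded half-up."""
    rows = []
    for r in results:
        row: dict = {
            "controlled_indicator": r.controlled_indicator,
        }
        for i, p in enumerate(r.stable_state.probs, start=1):
            row[f"P(S{i})"] = round_half_up(p, decimals)
        row["safety_score"] = round_half_up(r.safety_score, decimals)
        row["effective"] = r.effective
        row["rank"] = r.rank
        rows.append(row)
    return pd.DataFrame(rows)
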