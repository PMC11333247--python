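"""File readers/writers and the batch pipeline runner.

Stage assessments travel as CSV (``indicator_id,label,p_min,p_max,l_min,l_max``,
one file per stage) or as JSON/YAML documents with a ``stage_id`` and an
``assessments`` list. Risk matrices travel as JSON/YAML with ``p_levels``,
``l_levels``, ``states`` and ``cells`` keys. Machine outputs always carry full
precision; rounded "display" columns are additive, never a replacement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ._rounding import round_half_up
from .control import ControlScenarioResult, rank_controls, scenario_table
from .errors import EpiRiskError, ValidationError
from .markov import SteadyStateResult, steady_state
from .membership import (
    IndicatorAssessment,
    MembershipVector,
    StageAssessment,
    membership_table,
)
from .riskmatrix import RiskMatrixSpec, default_risk_matrix
from .transition import TransitionMatrix, build_stm

logger = logging.getLogger("epirisk")

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_assessments",
    "write_assessments",
    "membership_frame",
    "write_membership",
    "write_stm",
    "write_steady",
    "write_control_report",
    "run_pipeline",
    "load_config",
]

_ASSESSMENT_COLUMNS = ("indicator_id", "label", "p_min", "p_max", "l_min", "l_max")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return {"yml": "yaml"}.get(suffix, suffix)


# -- risk matrix ---------------------------------------------------------


def read_matrix(path: str | Path, fmt: str | None = None) -> RiskMatrixSpec:
    """Load a risk matrix from JSON/YAML; the name ``"default"`` is built in."""
    if str(path) == "default":
        return default_risk_matrix()
    path = Path(path)
    fmt = _infer_format(path, fmt)
    text = path.read_text()
    if fmt == "json":
        data = json.loads(text)
    elif fmt == "yaml":
        data = yaml.safe_load(text)
    else:
        raise ValidationError(f"unsupported matrix format {fmt!r} for {path}")
    try:
        return RiskMatrixSpec.from_dict(data)
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed risk matrix document: {exc}") from exc


def write_matrix(matrix: RiskMatrixSpec, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        path.write_text(json.dumps(matrix.to_dict(), indent=1) + "\n")
    elif fmt == "yaml":
        path.write_text(yaml.safe_dump(matrix.to_dict(), sort_keys=False))
    elif fmt == "csv":
        matrix.to_frame().to_csv(path, index=False)
    else:
        raise ValidationError(f"unsupported matrix format {fmt!r}")
    return path


# -- stage assessments ---------------------------------------------------


def _assessment_from_row(
    row: dict, where: str, p_levels: int | None, l_levels: int | None
) -> IndicatorAssessment:
    try:
        a = IndicatorAssessment(
            indicator_id=str(row["indicator_id"]),
            label=str(row.get("label", "") or ""),
            p_min=int(row["p_min"]),
            p_max=int(row["p_max"]),
            l_min=int(row["l_min"]),
            l_max=int(row["l_max"]),
        )
    except KeyError as exc:
        raise ValidationError(f"{where}: missing column {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: {exc}") from exc
    if p_levels is not None and a.p_max > p_levels:
        raise ValidationError(
            f"{where}: p_max={a.p_max} exceeds the {p_levels}-level probability axis"
        )
    if l_levels is not None and a.l_max > l_levels:
        raise ValidationError(
            f"{where}: l_max={a.l_max} exceeds the {l_levels}-level loss axis"
        )
    return a


def read_assessments(
    path: str | Path,
    fmt: str | None = None,
    stage_id: str | None = None,
    p_levels: int | None = 5,
    l_levels: int | None = 5,
) -> StageAssessment:
    """Load one stage of interval assessments from CSV/JSON/YAML.

    Rows are validated individually; errors name the offending row and rule.
    ``p_levels``/``l_levels`` bound-check the intervals against the target grid
    (pass ``None`` to defer that check to membership computation).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(path)
        sid = stage_id or path.stem
        rows = frame.to_dict("records")
    elif fmt in ("json", "yaml"):
        data = (
            json.loads(path.read_text()) if fmt == "json"
            else yaml.safe_load(path.read_text())
        )
        if not isinstance(data, dict) or "assessments" not in data:
            raise ValidationError(f"{path}: expected a document with 'assessments'")
        sid = stage_id or str(data.get("stage_id") or path.stem)
        rows = data["assessments"]
    else:
        raise ValidationError(f"unsupported assessment format {fmt!r} for {path}")

    assessments = [
        _assessment_from_row(
            row, f"{path.name} row {i} ({row.get('indicator_id', '?')})",
            p_levels, l_levels,
        )
        for i, row in enumerate(rows, start=1)
    ]
    try:
        return StageAssessment(sid, tuple(assessments))
    except ValidationError as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc


def write_assessments(
    stage: StageAssessment, path: str | Path, fmt: str | None = None
) -> Path:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = [
        {
            "indicator_id": a.indicator_id,
            "label": a.label,
            "p_min": a.p_min,
            "p_max": a.p_max,
            "l_min": a.l_min,
            "l_max": a.l_max,
        }
        for a in stage
    ]
    if fmt == "csv":
        pd.DataFrame(records, columns=_ASSESSMENT_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(
            json.dumps({"stage_id": stage.stage_id, "assessments": records}, indent=1)
            + "\n"
        )
    elif fmt == "yaml":
        path.write_text(
            yaml.safe_dump(
                {"stage_id": stage.stage_id, "assessments": records}, sort_keys=False
            )
        )
    else:
        raise ValidationError(f"unsupported assessment format {fmt!r}")
    return path


# -- result writers ------------------------------------------------------


def membership_frame(
    memberships: Sequence[MembershipVector], decimals: int | None = None
) -> pd.DataFrame:
    """Membership table, full precision plus optional rounded display columns."""
    n = memberships[0].n_states
    rows = []
    for m in memberships:
        row = {"indicator_id": m.indicator_id}
        row.update({f"mu_S{i+1}": m.mu[i] for i in range(n)})
        if decimals is not None:
            row.update(
                {f"mu_S{i+1}_{decimals}dp": v for i, v in enumerate(m.rounded(decimals))}
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_membership(
    memberships: Sequence[MembershipVector],
    path: str | Path,
    decimals: int | None = 4,
) -> Path:
    path = Path(path)
    membership_frame(memberships, decimals).to_csv(path, index=False)
    return path


def write_stm(tm: TransitionMatrix, path: str | Path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        path.write_text(json.dumps(tm.to_dict(), indent=1) + "\n")
    elif fmt == "csv":
        n = tm.n_states
        frame = pd.DataFrame(tm.stm, columns=[f"to_S{i+1}" for i in range(n)])
        frame.insert(0, "from", [f"S{i+1}" for i in range(n)])
        frame.to_csv(path, index=False)
    else:
        raise ValidationError(f"unsupported STM format {fmt!r}")
    return path


def write_steady(result: SteadyStateResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(result.to_dict(), indent=1) + "\n")
    return path


def write_control_report(
    results: Sequence[ControlScenarioResult],
    path: str | Path,
    fmt: str | None = None,
    decimals: int = 3,
) -> Path:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        scenario_table(results, decimals).to_csv(path, index=False)
    elif fmt == "json":
        payload = [
            {
                "controlled_indicator": r.controlled_indicator,
                "stable_state": list(r.stable_state.probs),
                "stable_state_rounded": list(r.stable_state.rounded(decimals)),
                "safety_score": r.safety_score,
                "baseline_score": r.baseline_score,
                "effective": r.effective,
                "rank": r.rank,
            }
            for r in results
        ]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValidationError(f"unsupported control-report format {fmt!r}")
    return path


# -- batch pipeline ------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one batch run over one or more stage files."""

    stage_paths: list[str]
    matrix_path: str = "default"
    output_dir: str = "epirisk_out"
    membership_decimals: int = 4
    distribution_decimals: int = 3
    degenerate_row_policy: str = "identity"
    steady_tol: float = 1e-12
    max_iter: int = 10**6
    seed: int | None = None
    output_format: str = "csv"

    def __post_init__(self) -> None:
        if self.degenerate_row_policy not in ("identity", "uniform", "error"):
            raise ValidationError(
                f"degenerate_row_policy must be identity|uniform|error, "
                f"got {self.degenerate_row_policy!r}"
            )
        if self.membership_decimals < 0 or self.distribution_decimals < 0:
            raise ValidationError("display decimals must be >= 0")
        if not self.stage_paths:
            raise ValidationError("at least one stage file is required")


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML mapping mirroring the CLI flags."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict[str, dict[str, str]]:
    """Run the full pipeline for every configured stage and write a report bundle.

    Per stage: membership table, raw + normalized STM, steady-state report and
    control ranking. Returns ``{stage_id: {artifact: path}}``. Any stage
    failure raises with a stage-scoped message (no partial bundle is reported
    for that stage).
    """
    matrix = read_matrix(config.matrix_path)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, str]] = {}

    for stage_path in config.stage_paths:
        stage = read_assessments(
            stage_path, p_levels=matrix.p_levels, l_levels=matrix.l_levels
        )
        sid = stage.stage_id
        try:
            memberships = membership_table(stage, matrix)
            tm = build_stm(stage, matrix, policy=config.degenerate_row_policy)
            steady = steady_state(
                tm, tol=config.steady_tol, max_iter=config.max_iter
            )
            controls = rank_controls(
                stage,
                matrix,
                policy=config.degenerate_row_policy,
                tol=config.steady_tol,
                max_iter=config.max_iter,
            )
        except EpiRiskError as exc:
            raise EpiRiskError(f"stage {sid!r}: {exc}") from exc

        logger.info(
            "stage %s: active_counts=%s degenerate_rows=%s regular=%s",
            sid, tm.active_counts, sorted(tm.degenerate_rows), steady.regular,
        )
        bundle = {
            "membership": str(
                write_membership(
                    memberships, out_dir / f"{sid}_membership.csv",
                    decimals=config.membership_decimals,
                )
            ),
            "stm": str(write_stm(tm, out_dir / f"{sid}_stm.json")),
            "steady": str(write_steady(steady, out_dir / f"{sid}_steady.json")),
            "control": str(
                write_control_report(
                    controls,
                    out_dir / f"{sid}_control.{config.output_format}",
                    decimals=config.distribution_decimals,
                )
            ),
        }
        written[sid] = bundle
    return written
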