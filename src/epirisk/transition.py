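"""Build the epidemic-risk state-transition matrix (STM) from memberships.

Row ``n`` of the raw weight matrix aggregates the indicators that can move the
system while it sits in state ``S_n``: exactly those whose membership in
``S_n`` is strictly positive. Their *full* membership vectors are summed, so
entry ``(n, m)`` is the total membership mass those indicators place on the
destination state ``S_m``. Row-normalizing yields the row-stochastic STM of the
discrete-time Markov chain over risk states.

Because every membership vector sums to 1, the raw row sum equals the number of
active indicators for that row, which is kept as ``active_counts``. A row with
no active indicator ("degenerate") has no evidence to leave its state; the
default policy keeps the chain total by inserting an identity self-loop, with
``uniform`` and ``error`` policies selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rounding import round_half_up
from .errors import DegenerateRowError, InputDomainError
from .membership import MembershipVector, membership_table, memberships_as_array
from .membership import StageAssessment
from .riskmatrix import RiskMatrixSpec

__all__ = [
    "TransitionMatrix",
    "raw_transition_weights",
    "normalize_rows",
    "build_stm",
    "DEGENERATE_ROW_POLICIES",
]

DEGENERATE_ROW_POLICIES = ("identity", "uniform", "error")


@dataclass
class TransitionMatrix:
    """Raw weights and the row-stochastic STM, with aggregation metadata.

    ``degenerate_rows`` holds 1-based state indices of rows that had all-zero
    raw weight and were filled in by the policy.
    """

    stm: np.ndarray
    raw: np.ndarray
    stage_id: str | None = None
    active_counts: tuple[int, ...] | None = None
    degenerate_rows: frozenset[int] = frozenset()
    policy: str = "identity"

    def __post_init__(self) -> None:
        self.stm = np.asarray(self.stm, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        n = self.stm.shape[0]
        if self.stm.shape != (n, n) or self.raw.shape != (n, n):
            raise InputDomainError(
                f"expected square matrices of equal size, got stm {self.stm.shape} "
                f"and raw {self.raw.shape}"
            )
        rowsums = self.stm.sum(axis=1)
        if np.any(self.stm < -1e-15) or np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise InputDomainError(
                f"stm is not row-stochastic (row sums {rowsums})"
            )
        self.degenerate_rows = frozenset(int(i) for i in self.degenerate_rows)

    @property
    def n_states(self) -> int:
        return self.stm.shape[0]

    def rounded(self, decimals: int = 4) -> list[list[float]]:
        """Display view of the STM, round-half-up."""
        return [[round_half_up(v, decimals) for v in row] for row in self.stm]

    def to_dict(self) -> dict:
        return {
            "stage_id": self.stage_id,
            "stm": self.stm.tolist(),
            "stm_rounded_4dp": self.rounded(4),
            "raw": self.raw.tolist(),
            "active_counts": list(self.active_counts or ()),
            "degenerate_rows": sorted(self.degenerate_rows),
            "policy": self.policy,
        }


def raw_transition_weights(
    memberships: Sequence[MembershipVector],
) -> np.ndarray:
    """Raw (pre-normalization) transition weights from a set of memberships.

    Entry ``(n, m)`` sums ``mu_Sm(a_j)`` over the indicators ``j`` whose
    ``mu_Sn(a_j)`` is strictly positive. Strictness needs no tolerance:
    memberships are exact cell-count fractions, so a zero is a true zero.
    """
    if not memberships:
        raise InputDomainError("at least one membership vector is required")
    mus = memberships_as_array(memberships)  # indicators x states
    n_states = mus.shape[1]
    raw = np.zeros((n_states, n_states))
    for n in range(n_states):
        active = mus[:, n] > 0
        raw[n] = mus[active].sum(axis=0)
    return raw


def _active_counts(raw: np.ndarray) -> tuple[int, ...]:
    # each active indicator contributes a vector summing to exactly 1
    return tuple(int(round(s)) for s in raw.sum(axis=1))


def normalize_rows(
    raw: np.ndarray,
    policy: str = "identity",
    stage_id: str | None = None,
    active_counts: tuple[int, ...] | None = None,
) -> TransitionMatrix:
    """Row-normalize raw weights into a row-stochastic STM.

    All-zero rows are handled by ``policy``: ``identity`` (default) inserts a
    self-loop, ``uniform`` spreads mass evenly, ``error`` raises
    :class:`~epirisk.errors.DegenerateRowError`. Affected 1-based row indices
    are recorded in ``degenerate_rows`` and a warning is emitted.
    """
    if policy not in DEGENERATE_ROW_POLICIES:
        raise InputDomainError(
            f"unknown degenerate-row policy {policy!r}; "
            f"choose from {DEGENERATE_ROW_POLICIES}"
        )
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise InputDomainError(f"raw weights must be square, got shape {raw.shape}")
    if np.any(raw < 0):
        raise InputDomainError("raw transition weights must be nonnegative")

    n = raw.shape[0]
    stm = np.zeros_like(raw)
    degenerate: set[int] = set()
    for i in range(n):
        s = raw[i].sum()
        if s > 0:
            stm[i] = raw[i] / s
        else:
            degenerate.add(i + 1)
            if policy == "error":
                raise DegenerateRowError(
                    f"row {i + 1} has all-zero raw weight "
                    f"(no indicator has positive membership in state {i + 1})"
                )
            if policy == "identity":
                stm[i, i] = 1.0
            else:  # uniform
                stm[i] = 1.0 / n
    if degenerate:
        warnings.warn(
            f"degenerate raw rows {sorted(degenerate)} filled by "
            f"{policy!r} policy",
            stacklevel=2,
        )
    return TransitionMatrix(
        stm=stm,
        raw=raw,
        stage_id=stage_id,
        active_counts=active_counts if active_counts is not None else _active_counts(raw),
        degenerate_rows=frozenset(degenerate),
        policy=policy,
    )


def build_stm(
    stage: StageAssessment,
    matrix: RiskMatrixSpec,
    policy: str = "identity",
) -> TransitionMatrix:
    """Full pipeline for one stage: memberships -> raw weights -> STM."""
    memberships = membership_table(stage, matrix)
    raw = raw_transition_weights(memberships)
    return normalize_rows(raw, policy=policy, stage_id=stage.stage_id)
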