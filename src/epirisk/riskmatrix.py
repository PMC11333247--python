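"""Discrete probability x loss risk matrix mapping level pairs to risk states.

The grid has ``p_levels`` occurrence-probability levels and ``l_levels``
loss-severity levels, both 1-based integers. Each cell carries exactly one
ordinal risk state. The packaged default is the 5x5 four-state grid used for
hospital epidemic risk:

* ``S1`` -- risk disappearance state (risk almost non-existent, losses negligible),
* ``S2`` -- risk potential state (risk exists, small recoverable losses),
* ``S3`` -- risk critical state (risk clearly present, on the verge of outbreak),
* ``S4`` -- risk outbreak state (risk fully erupted, losses hard to recover).

The cell-to-state mapping is stored as an explicit table, never derived from the
``p*l`` score: on the default grid cell (P=4, L=1) is S2 while (P=2, L=2) is S1
although both score 4, so any formulaic reconstruction would be wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import InputDomainError

__all__ = [
    "RiskState",
    "RiskMatrixSpec",
    "Diagnostic",
    "default_risk_matrix",
    "DEFAULT_STATES",
]


@dataclass(frozen=True, order=True)
class RiskState:
    """One ordinal risk state; higher ``index`` means more dangerous."""

    index: int
    label: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.index < 1:
            raise InputDomainError(f"state index must be >= 1, got {self.index}")


DEFAULT_STATES: tuple[RiskState, ...] = (
    RiskState(1, "S1", "risk disappearance state"),
    RiskState(2, "S2", "risk potential state"),
    RiskState(3, "S3", "risk critical state"),
    RiskState(4, "S4", "risk outbreak state"),
)

# Default grid, one row per probability level P (descending as conventionally
# printed), entries are state indices for loss levels L = 1..5.
_DEFAULT_GRID: dict[int, tuple[int, ...]] = {
    5: (2, 3, 4, 4, 4),
    4: (2, 2, 3, 4, 4),
    3: (1, 2, 2, 3, 4),
    2: (1, 1, 2, 2, 3),
    1: (1, 1, 1, 2, 2),
}


@dataclass(frozen=True)
class Diagnostic:
    """One structural finding from :meth:`RiskMatrixSpec.validate`."""

    kind: str  # missing_cell | duplicate_cell | unknown_state | unused_state | bad_cell
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


@dataclass
class RiskMatrixSpec:
    """A labelled P x L grid.

    ``cell_state`` maps each ``(p, l)`` pair to a state index. Construction
    checks only the state list (contiguous indices 1..n, n >= 2); completeness
    of the cell table is reported by :meth:`validate` so that broken inputs can
    be diagnosed rather than rejected wholesale.
    """

    p_levels: int
    l_levels: int
    states: tuple[RiskState, ...] = DEFAULT_STATES
    cell_state: dict[tuple[int, int], int] = field(default_factory=dict)
    level_definitions: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_levels < 1 or self.l_levels < 1:
            raise InputDomainError(
                f"level counts must be positive, got p_levels={self.p_levels}, "
                f"l_levels={self.l_levels}"
            )
        self.states = tuple(sorted(self.states, key=lambda s: s.index))
        indices = [s.index for s in self.states]
        if len(self.states) < 2:
            raise InputDomainError("a risk matrix needs at least 2 states")
        if indices != list(range(1, len(self.states) + 1)):
            raise InputDomainError(
                f"state indices must be contiguous 1..n, got {indices}"
            )
        self.cell_state = {
            (int(p), int(l)): int(s) for (p, l), s in self.cell_state.items()
        }

    # -- basic queries ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def cells(self) -> tuple[tuple[int, int], ...]:
        """All grid cells in row-major (p, l) order."""
        return tuple(
            (p, l)
            for p in range(1, self.p_levels + 1)
            for l in range(1, self.l_levels + 1)
        )

    def state(self, key: int | str | RiskState) -> RiskState:
        """Resolve a state by index, label or identity."""
        if isinstance(key, RiskState):
            key = key.index
        for s in self.states:
            if s.index == key or s.label == key:
                return s
        raise InputDomainError(
            f"unknown state {key!r}; known: "
            + ", ".join(f"{s.index}({s.label})" for s in self.states)
        )

    def _check_level(self, value: int, axis: str, bound: int) -> None:
        if not 1 <= value <= bound:
            raise InputDomainError(
                f"{axis} level {value} outside 1..{bound}"
            )

    def classify_cell(self, p: int, l: int) -> RiskState:
        """Return the risk state of cell ``(p, l)``."""
        self._check_level(p, "probability", self.p_levels)
        self._check_level(l, "loss", self.l_levels)
        try:
            return self.state(self.cell_state[(p, l)])
        except KeyError:
            raise InputDomainError(f"cell ({p},{l}) has no state assigned") from None

    def state_region(self, state: int | str | RiskState) -> frozenset[tuple[int, int]]:
        """All cells labelled with ``state`` (the state's area in the matrix)."""
        s = self.state(state)
        return frozenset(c for c, idx in self.cell_state.items() if idx == s.index)

    def state_counts(self) -> dict[str, int]:
        """Number of grid cells per state label."""
        return {s.label: len(self.state_region(s)) for s in self.states}

    # -- validation ------------------------------------------------------

    def validate(self) -> list[Diagnostic]:
        """Structural diagnostics; an empty list means the matrix is sound."""
        findings: list[Diagnostic] = []
        known = {s.index for s in self.states}
        for cell in self.cells:
            if cell not in self.cell_state:
                findings.append(
                    Diagnostic("missing_cell", f"cell {cell} is not mapped to a state")
                )
        for cell, idx in sorted(self.cell_state.items()):
            p, l = cell
            if not (1 <= p <= self.p_levels and 1 <= l <= self.l_levels):
                findings.append(
                    Diagnostic(
                        "bad_cell",
                        f"cell {cell} lies outside the "
                        f"{self.p_levels}x{self.l_levels} grid",
                    )
                )
            if idx not in known:
                findings.append(
                    Diagnostic(
                        "unknown_state",
                        f"cell {cell} references undefined state index {idx}",
                    )
                )
        used = set(self.cell_state.values())
        for s in self.states:
            if s.index not in used:
                findings.append(
                    Diagnostic(
                        "unused_state",
                        f"state {s.index} ({s.label}) labels no cell",
                    )
                )
        return findings

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "p_levels": self.p_levels,
            "l_levels": self.l_levels,
            "states": [
                {"index": s.index, "label": s.label, "description": s.description}
                for s in self.states
            ],
            "cells": [
                {"p": p, "l": l, "state": idx}
                for (p, l), idx in sorted(self.cell_state.items())
            ],
            "level_definitions": self.level_definitions,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RiskMatrixSpec":
        states = tuple(
            RiskState(int(s["index"]), str(s.get("label", f"S{s['index']}")),
                      str(s.get("description", "")))
            for s in data["states"]
        )
        cell_state = {
            (int(c["p"]), int(c["l"])): int(c["state"]) for c in data["cells"]
        }
        return cls(
            p_levels=int(data["p_levels"]),
            l_levels=int(data["l_levels"]),
            states=states,
            cell_state=cell_state,
            level_definitions=dict(data.get("level_definitions", {})),
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per cell with the informational ``score = p*l`` column."""
        rows = [
            {"p": p, "l": l, "score": p * l, "state": self.state(idx).label}
            for (p, l), idx in sorted(self.cell_state.items())
        ]
        return pd.DataFrame(rows, columns=["p", "l", "score", "state"])


def default_risk_matrix() -> RiskMatrixSpec:
    """The packaged default 5x5 grid with four states (S1..S4)."""
    cell_state = {
        (p, l): state
        for p, row in _DEFAULT_GRID.items()
        for l, state in enumerate(row, start=1)
    }
    return RiskMatrixSpec(
        p_levels=5, l_levels=5, states=DEFAULT_STATES, cell_state=cell_state
    )


def classify_cell(p: int, l: int, matrix: RiskMatrixSpec) -> RiskState:
    """Functional alias for :meth:`RiskMatrixSpec.classify_cell`."""
    return matrix.classify_cell(p, l)


def state_region(
    matrix: RiskMatrixSpec, state: int | str | RiskState
) -> frozenset[tuple[int, int]]:
    """Functional alias for :meth:`RiskMatrixSpec.state_region`."""
    return matrix.state_region(state)


def validate_matrix(matrix: RiskMatrixSpec) -> list[Diagnostic]:
    """Functional alias for :meth:`RiskMatrixSpec.validate`."""
    return matrix.validate()
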