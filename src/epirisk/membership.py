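"""State memberships of interval-valued indicator assessments.

Experts judge each risk indicator ``a_j`` with integer level ranges
``[p_min, p_max] x [l_min, l_max]`` rather than point scores. The rectangle of
grid cells covered by those ranges is intersected with each state's region of
the risk matrix; the membership of ``a_j`` in state ``S_n`` is

    mu_Sn(a_j) = |rectangle cells labelled S_n| / |rectangle cells|

Bounds are inclusive and cells are counted discretely, which is the unique
reading that reproduces the published membership tables (e.g. a 3x2 rectangle
with 3 S2-cells gives exactly 0.5). Memberships are exact rationals with the
rectangle size as denominator; they are stored as integer counts and only
converted to floats on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np

from ._rounding import round_vector
from .errors import InputDomainError, ValidationError
from .riskmatrix import RiskMatrixSpec

__all__ = [
    "IndicatorAssessment",
    "StageAssessment",
    "MembershipVector",
    "assessment_cells",
    "membership_vector",
    "membership_table",
]


@dataclass(frozen=True)
class IndicatorAssessment:
    """One indicator's interval judgment ``[p_min, p_max] x [l_min, l_max]``.

    A degenerate interval (min == max) is a legal point judgment. Upper bounds
    are validated against a concrete matrix only when memberships are computed,
    so an assessment can be built before the grid is chosen.
    """

    indicator_id: str
    p_min: int
    p_max: int
    l_min: int
    l_max: int
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("p_min", "p_max", "l_min", "l_max"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise InputDomainError(
                    f"{self.indicator_id}: {name} must be an integer level, got {v!r}"
                )
            object.__setattr__(self, name, int(v))
        if self.p_min < 1 or self.l_min < 1:
            raise InputDomainError(
                f"{self.indicator_id}: levels are 1-based, got "
                f"p_min={self.p_min}, l_min={self.l_min}"
            )
        if self.p_min > self.p_max:
            raise InputDomainError(
                f"{self.indicator_id}: p_min <= p_max violated "
                f"({self.p_min} > {self.p_max})"
            )
        if self.l_min > self.l_max:
            raise InputDomainError(
                f"{self.indicator_id}: l_min <= l_max violated "
                f"({self.l_min} > {self.l_max})"
            )

    def cells(self) -> frozenset[tuple[int, int]]:
        """All integer cells of the closed rectangle Square(a_j)."""
        return frozenset(
            (p, l)
            for p in range(self.p_min, self.p_max + 1)
            for l in range(self.l_min, self.l_max + 1)
        )

    @property
    def size(self) -> int:
        return (self.p_max - self.p_min + 1) * (self.l_max - self.l_min + 1)


def assessment_cells(a: IndicatorAssessment) -> frozenset[tuple[int, int]]:
    """Functional alias for :meth:`IndicatorAssessment.cells`."""
    return a.cells()


@dataclass(frozen=True)
class StageAssessment:
    """The full set of indicator assessments for one epidemic stage.

    The list length is the number of indicators aggregated into each transition
    row (the elicitation's ``total``).
    """

    stage_id: str
    assessments: tuple[IndicatorAssessment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assessments", tuple(self.assessments))
        if not self.assessments:
            raise ValidationError(f"stage {self.stage_id!r} has no assessments")
        ids = [a.indicator_id for a in self.assessments]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(
                f"stage {self.stage_id!r}: duplicate indicator ids {sorted(dupes)}"
            )

    @property
    def total(self) -> int:
        return len(self.assessments)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(a.indicator_id for a in self.assessments)

    def __iter__(self) -> Iterator[IndicatorAssessment]:
        return iter(self.assessments)

    def get(self, indicator_id: str) -> IndicatorAssessment:
        for a in self.assessments:
            if a.indicator_id == indicator_id:
                return a
        raise InputDomainError(
            f"stage {self.stage_id!r} has no indicator {indicator_id!r}; "
            f"known: {list(self.indicator_ids)}"
        )

    def replace(self, assessment: IndicatorAssessment) -> "StageAssessment":
        """A copy of the stage with one indicator's assessment swapped in place."""
        self.get(assessment.indicator_id)  # raise if unknown
        return StageAssessment(
            self.stage_id,
            tuple(
                assessment if a.indicator_id == assessment.indicator_id else a
                for a in self.assessments
            ),
        )


@dataclass(frozen=True)
class MembershipVector:
    """mu_Sn(a_j) for all states n, stored exactly as cell counts / denominator."""

    indicator_id: str
    counts: tuple[int, ...]
    denominator: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if self.denominator < 1:
            raise InputDomainError("denominator must be a positive cell count")
        if any(c < 0 for c in self.counts):
            raise InputDomainError("cell counts must be nonnegative")
        if sum(self.counts) != self.denominator:
            raise InputDomainError(
                f"{self.indicator_id}: counts {self.counts} do not sum to the "
                f"rectangle size {self.denominator}"
            )

    @property
    def n_states(self) -> int:
        return len(self.counts)

    @property
    def mu(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / float(self.denominator)

    def as_fractions(self) -> tuple[Fraction, ...]:
        return tuple(Fraction(c, self.denominator) for c in self.counts)

    def rounded(self, decimals: int = 4) -> tuple[float, ...]:
        """Display view at fixed decimals, round-half-up."""
        return round_vector(self.mu, decimals)


def membership_vector(
    a: IndicatorAssessment, matrix: RiskMatrixSpec
) -> MembershipVector:
    """Membership of one interval assessment in every state of ``matrix``."""
    if a.p_max > matrix.p_levels:
        raise InputDomainError(
            f"{a.indicator_id}: p_max={a.p_max} exceeds the matrix's "
            f"{matrix.p_levels} probability levels"
        )
    if a.l_max > matrix.l_levels:
        raise InputDomainError(
            f"{a.indicator_id}: l_max={a.l_max} exceeds the matrix's "
            f"{matrix.l_levels} loss levels"
        )
    counts = [0] * matrix.n_states
    for p, l in a.cells():
        counts[matrix.classify_cell(p, l).index - 1] += 1
    return MembershipVector(a.indicator_id, tuple(counts), a.size)


def membership_table(
    stage: StageAssessment, matrix: RiskMatrixSpec
) -> list[MembershipVector]:
    """One membership vector per indicator, in input order."""
    out = []
    for a in stage:
        try:
            out.append(membership_vector(a, matrix))
        except InputDomainError as exc:
            raise InputDomainError(
                f"stage {stage.stage_id!r}, indicator {a.indicator_id!r}: {exc}"
            ) from exc
    return out


def memberships_as_array(memberships: Sequence[MembershipVector]) -> np.ndarray:
    """Stack membership vectors into an (indicators x states) float array."""
    n = {m.n_states for m in memberships}
    if len(n) != 1:
        raise InputDomainError(f"inconsistent state counts {sorted(n)}")
    return np.vstack([m.mu for m in memberships])
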