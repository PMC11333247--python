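"""Evolution and stationary analysis of the risk-state Markov chain.

The state distribution is a probability row vector ``P^t`` over risk states;
``k`` transitions give ``P^{t+k} = P^t . STM^k``. The long-run ("stable") risk
state is the stationary distribution, computed by power iteration to mirror
that narrative, with a left-eigenvector solve available as an independent
cross-check and a seeded trajectory simulator as a stochastic one.

For a regular chain (some power of the STM strictly positive) the stationary
distribution is unique and independent of the initial distribution; regularity
is verified rather than assumed, and non-regular chains are reported as such
with whatever (possibly initial-dependent) limit the iteration reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rounding import round_vector
from .errors import InputDomainError
from .transition import TransitionMatrix

__all__ = [
    "StateDistribution",
    "SteadyStateResult",
    "evolve",
    "steady_state",
    "is_regular",
    "stationary_eigenvector",
    "simulate_chain",
]


@dataclass(frozen=True)
class StateDistribution:
    """A probability vector over risk states, optionally tagged with stage/time."""

    probs: tuple[float, ...]
    stage_id: str | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise InputDomainError("a distribution needs at least 2 states")
        if np.any(p < -1e-12):
            raise InputDomainError(f"negative probability in {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise InputDomainError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))

    @classmethod
    def uniform(cls, n_states: int, **kw) -> "StateDistribution":
        return cls(tuple([1.0 / n_states] * n_states), **kw)

    @classmethod
    def one_hot(cls, n_states: int, state: int, **kw) -> "StateDistribution":
        """Point mass on 1-based ``state``."""
        if not 1 <= state <= n_states:
            raise InputDomainError(f"state {state} outside 1..{n_states}")
        p = [0.0] * n_states
        p[state - 1] = 1.0
        return cls(tuple(p), **kw)

    @property
    def n_states(self) -> int:
        return len(self.probs)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs)

    def rounded(self, decimals: int = 3) -> tuple[float, ...]:
        return round_vector(self.probs, decimals)


@dataclass
class SteadyStateResult:
    """Outcome of the stationary-distribution solve."""

    distribution: StateDistribution
    iterations: int
    converged: bool
    regular: bool
    residual: float  # L1 norm of pi.STM - pi

    def to_dict(self) -> dict:
        return {
            "stage_id": self.distribution.stage_id,
            "stable_state": list(self.distribution.probs),
            "stable_state_3dp": list(self.distribution.rounded(3)),
            "iterations": self.iterations,
            "converged": self.converged,
            "regular": self.regular,
            "residual": self.residual,
        }


def _as_matrix(stm: TransitionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(stm, TransitionMatrix):
        return stm.stm
    m = np.asarray(stm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputDomainError(f"transition matrix must be square, got {m.shape}")
    if np.any(m < -1e-15) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
        raise InputDomainError("transition matrix is not row-stochastic")
    return m


def _stage_of(stm: TransitionMatrix | np.ndarray) -> str | None:
    return stm.stage_id if isinstance(stm, TransitionMatrix) else None


def evolve(
    dist: StateDistribution, stm: TransitionMatrix | np.ndarray, k: int = 1
) -> StateDistribution:
    """``k``-step evolution ``P^{t+k} = P^t . STM^k``; ``k = 0`` is the input."""
    if k < 0:
        raise InputDomainError(f"step count k must be >= 0, got {k}")
    m = _as_matrix(stm)
    if dist.n_states != m.shape[0]:
        raise InputDomainError(
            f"distribution has {dist.n_states} states but STM is {m.shape[0]}x"
            f"{m.shape[0]}"
        )
    p = dist.array @ np.linalg.matrix_power(m, k)
    p = p / p.sum()  # wash out matrix-power float drift
    return StateDistribution(
        tuple(p), stage_id=dist.stage_id, k=(dist.k or 0) + k
    )


def is_regular(
    stm: TransitionMatrix | np.ndarray, k_max: int = 64, tol: float = 1e-12
) -> tuple[bool, dict]:
    """Whether some power ``<= k_max`` of the STM is strictly positive.

    Uses repeated squaring; also reports whether the rows of high powers have
    collapsed onto a common vector (the ergodic limit), which guards the claim
    that the stable state does not depend on the initial distribution.
    """
    if k_max < 1:
        raise InputDomainError(f"k_max must be >= 1, got {k_max}")
    m = _as_matrix(stm)
    power = m.copy()
    k = 1
    positive_at: int | None = None
    while k <= k_max:
        if positive_at is None and np.all(power > 0):
            positive_at = k
        spread = float(np.max(power.max(axis=0) - power.min(axis=0)))
        if positive_at is not None and spread < max(tol, 1e-13):
            break
        power = power @ power
        k *= 2
    rows_converged = positive_at is not None and spread < max(tol, 1e-13)
    diagnostics = {
        "positive_power": positive_at,
        "checked_up_to": min(k, k_max),
        "row_spread": spread,
        "rows_converged": rows_converged,
    }
    return positive_at is not None, diagnostics


def steady_state(
    stm: TransitionMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10**6,
    initial: StateDistribution | None = None,
) -> SteadyStateResult:
    """Stationary distribution by power iteration from ``initial`` (default uniform).

    Iterates ``pi <- pi.STM`` until the L1 change drops below ``tol``. A
    period-2 oscillation is detected and resolved to the Cesaro average of the
    two accumulation points. Non-convergence within ``max_iter`` yields a
    ``converged=False`` result rather than an exception.
    """
    m = _as_matrix(stm)
    n = m.shape[0]
    if initial is None:
        pi = np.full(n, 1.0 / n)
    else:
        if initial.n_states != n:
            raise InputDomainError(
                f"initial distribution has {initial.n_states} states, STM has {n}"
            )
        pi = initial.array.copy()

    converged = False
    iterations = 0
    prev = pi
    for iterations in range(1, max_iter + 1):
        nxt = pi @ m
        if np.abs(nxt - pi).sum() < tol:
            pi = nxt
            converged = True
            break
        if iterations > 2 and np.abs(nxt - prev).sum() < tol:
            # period-2 oscillation: return the Cesaro average of the cycle
            pi = (nxt + pi) / 2.0
            break
        prev, pi = pi, nxt

    pi = pi / pi.sum()
    residual = float(np.abs(pi @ m - pi).sum())
    regular, _ = is_regular(m)
    dist = StateDistribution(tuple(pi), stage_id=_stage_of(stm))
    return SteadyStateResult(
        distribution=dist,
        iterations=iterations,
        converged=converged,
        regular=regular,
        residual=residual,
    )


def stationary_eigenvector(stm: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Dominant left eigenvector, normalized to a distribution (cross-check path)."""
    m = _as_matrix(stm)
    vals, vecs = np.linalg.eig(m.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9):
        raise InputDomainError("dominant eigenvector is not sign-definite")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def simulate_chain(
    stm: TransitionMatrix | np.ndarray,
    n_steps: int,
    initial_state: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Occupancy fractions of a simulated trajectory (stochastic oracle).

    Draws ``n_steps`` categorical transitions starting from the 1-based
    ``initial_state`` and returns the fraction of steps spent in each state.
    The same seed always reproduces the same trajectory.
    """
    m = _as_matrix(stm)
    n = m.shape[0]
    if n_steps < 1:
        raise InputDomainError(f"n_steps must be >= 1, got {n_steps}")
    if not 1 <= initial_state <= n:
        raise InputDomainError(f"initial_state {initial_state} outside 1..{n}")
    rng = np.random.default_rng(seed)
    # draw all uniforms at once; walk through cumulative rows
    cum = np.cumsum(m, axis=1)
    u = rng.random(n_steps)
    counts = np.zeros(n, dtype=np.int64)
    state = initial_state - 1
    for i in range(n_steps):
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, n - 1)  # guard float edge at u ~ 1.0
        counts[state] += 1
    return counts / float(n_steps)
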