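# Methods

## Model

Epidemic risk is treated as a stochastic process over an ordinal state space
`S1 < S2 < … < Sn` (default n = 4: risk disappearance, risk potential, risk
critical, risk outbreak). The process is assumed to be a time-homogeneous
discrete-time Markov chain: the probability of moving between risk states
depends only on the current state, and the transition matrix built from one
stage's elicitation is held fixed while that stage's long-run behaviour is
computed. Stages (non-epidemic, early epidemic, outbreak) are modelled
independently — there is no between-stage dynamics.

### Risk matrix

States are anchored to a `P × L` grid of occurrence-probability levels
(1 = almost impossible … 5 = almost inevitable) and loss-severity levels
(1 = negligible … 5 = extremely serious). The cell→state labelling is stored
as an explicit table because it is not reconstructible from the score `P·L`:
on the default grid cells (4, 1) and (2, 2) both score 4 yet carry different
states. Any grid size and state count ≥ 2 are supported; the 5 × 5/4-state
instance is the packaged default.

### Interval memberships

An indicator's judgment is a rectangle of grid cells
`[p_min, p_max] × [l_min, l_max]` with inclusive integer bounds; a point
judgment (min = max) is legal. Membership in state `S_n` is the fraction of
rectangle cells labelled `S_n`. The "area" in the membership quotient is
implemented as **discrete cell counting**: a continuous-area reading has no
unique half-open/closed convention, whereas cell counting is the single
interpretation that reproduces the packaged reference membership tables
exactly (a 3 × 2 rectangle with three `S2` cells gives 3/6 = 0.5000).
Memberships are exact rationals (integer counts over the rectangle size) and
are kept that way internally; floats appear only at the display boundary.

### Transition-matrix construction

Raw transition weight row `n` sums the **full membership vectors** of exactly
those indicators whose membership in `S_n` is strictly positive; entry
`(n, m)` is therefore the total membership mass those indicators place on
destination `S_m`. Strict positivity needs no tolerance because memberships
are exact fractions. Because every membership vector sums to 1, the raw row
sum equals the number of "active" indicators for that row, which is reported
as `active_counts`. Row-normalizing gives the row-stochastic STM.

A published formula that sums only `μ_Sn(a_j)` itself, independent of the
destination state, cannot yield the reference matrices; the subset-of-full-
vectors rule above is the one construction consistent with them, and the
package implements that rule. The reference matrices print their third and
fourth rows interleaved column-wise; the package always works with (and
stores goldens in) plain row order.

**Degenerate rows.** A state supported by no indicator produces an all-zero
raw row. The default policy inserts an identity self-loop (no evidence to
leave the state), recorded in `degenerate_rows` with a warning; `uniform` and
`error` policies are selectable. The packaged inputs never hit this case, but
the contract must be total for synthetic and user data.

### Stable risk state

The state distribution evolves as `P^{t+k} = P^t · STM^k`. The stable state is
computed by power iteration (mirroring that narrative), default initial
distribution uniform, stopping when the L1 change per step falls below
`tol = 1e-12` (capped at 1e6 iterations; non-convergence is reported in the
result object, never raised). A period-2 oscillation is detected by comparing
alternate iterates and resolved to the Cesàro average of the two accumulation
points, flagged `converged=False`.

Regularity (some matrix power strictly positive, checked by repeated squaring
up to the 64th power, plus collapse of the rows of high powers onto a common
vector) is verified rather than assumed; only for regular chains is the limit
guaranteed initial-independent. Two independent cross-checks are wired into
the test suite: the dominant left eigenvector (via `numpy.linalg.eig`) and a
seeded Monte-Carlo trajectory whose occupancy fractions must approach the
stationary vector at the usual `n^(-1/2)` rate.

## Control scenarios

A control on indicator `a_j` decrements `p_min` and `p_max` by one level each,
floored at level 1 (a bound at the floor does not move; the operation is
idempotent there). Loss levels are never decremented by default — short-term
interventions change how likely a risk is, not how much damage it would cause —
but a loss-side decrement exists behind an explicit flag, as does a
multi-indicator generalization. The floor rule is applied at every stage for
totality (on the packaged inputs it can only bind at the non-epidemic stage,
where `p_min = 1` occurs).

Scenarios are scored by the safety score `P̂(S1) + P̂(S2)` and compared to the
uncontrolled baseline with **strict** inequality; ranking is by descending
safety score with ties broken by indicator input order.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `p_levels`, `l_levels` | 5, 5 | grid size of the risk matrix (1-based integer levels) |
| `n_states` | 4 | ordinal risk states; any ≥ 2 with a contiguous 1..n indexing |
| `policy` | `identity` | degenerate (all-zero) transition-row handling: identity / uniform / error |
| `tol` | 1e-12 | L1 stopping tolerance of the power iteration |
| `max_iter` | 1e6 | iteration cap; exceeded ⇒ `converged=False` result |
| `k_max` | 64 | highest matrix power probed by the regularity check |
| `levels` | 1 | control decrement size |
| display decimals | 4 (memberships, STM), 3 (distributions) | round-half-up display views; internal values stay full precision |

Rounding for display and golden comparison is **half-up** (matching the
reference tables' formatting), implemented with `decimal` rather than
Python's banker's `round`.

## Packaged reference data and goldens

The package ships the reference elicitation (nine indicators × three stages of
interval judgments), the default risk matrix, and every downstream printed
result stored verbatim at its printed precision together with its rounding
rule. Goldens are always *regenerated* by the pipeline during verification
(`epirisk reproduce-paper`, `fixtures.verify_printed_results`) and compared at
one unit in the last printed decimal: the source tables contain print
quirks (0.6666 for an exact 2/3; a control table evidently computed from 3-dp
rounded intermediates, off by ≤ 5e-4 from the exact pipeline), so exact
re-rounding equality would test the source's formatter rather than the math.
The control tables for the non-epidemic and outbreak stages are corrupted
duplicates of the early-epidemic table in the available source; for those two
stages only the prose conclusions (which controls are effective, which rank
first) are verified, as set/ordering checks rather than numeric goldens.

## Synthetic data

`fixtures.random_stage` draws, per indicator, interval bounds uniformly over
all valid ordered level pairs on each axis, seeded and reproducible. It
emulates the *structure* of an elicitation (valid nested intervals on the
right grid), not its sociology: real expert panels produce correlated,
consensus-driven, typically narrower intervals. Property tests on random
stages therefore establish structural invariants (row-stochasticity,
normalization, floor behaviour) — not calibration of the method against real
elicitations, which only the packaged reference stages speak to.

## Numerical choices and edge cases

- Memberships: exact integer arithmetic; normalization holds as an identity,
  not within a tolerance.
- STM rows sum to 1 within 1e-9 (construction guarantees ~1e-16).
- Power iteration on a 4-state chain converges in a few hundred iterations at
  `tol = 1e-12`; the fixed-point residual `‖πSTM − π‖₁` is reported and is
  ≤ 1e-10 for every converged result.
- Matrix powers in `evolve` are renormalized after `numpy.linalg.matrix_power`
  to wash out float drift for large `k`.
- The trajectory simulator draws all uniforms up front from
  `numpy.random.default_rng(seed)` and walks cumulative rows; identical seeds
  give identical trajectories.

## Known limitations

- Indicators are equally weighted; the aggregation has no notion of indicator
  importance or expert weight.
- Single-stage, time-homogeneous chains only: no stage-switching dynamics,
  continuous-time chains, hitting times or absorption analysis.
- Expert elicitation itself (building a consensus interval from a panel) is
  out of scope; the package consumes one interval per indicator.
- Control scenarios explore one-level probability decrements (optionally loss
  decrements, multi-indicator combinations); there is no optimization over
  control budgets or costs.
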