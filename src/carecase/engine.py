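"""Discrete-time Markov cohort engine with a micro-simulation oracle.

The models in this package (annual-cycle breast-cancer screening, monthly-cycle
asthma medication use) are both discrete-time Markov cohort models: a state
occupancy vector is propagated through per-cycle transition matrices and
multiplied by per-cycle rewards on named channels (utility, costs, days, ...).

Reward timing convention
------------------------
Rewards are credited at the end of each cycle, after that cycle's transition
has been resolved: the cycle's state reward is the reward of the state the
person *ends* the cycle in, and one-off transition rewards are credited on the
specific transition taken during the cycle.  There is no half-cycle
correction.  With a survival channel that pays 1 per cycle in every live
state, a two-state chain with per-cycle death probability p therefore yields a
life expectancy of sum_{t=1..n} (1-p)^t on the 0-to-n scale.

The cycle of death accrues ``death_cycle_fraction`` (default 0.5) of the
*utility* reward of the state the person died from, implementing part-year /
part-month quality-of-life accrual in the cycle of death.  Other channels
receive no automatic death-cycle credit.

``run_cohort`` propagates expectations exactly (no sampling); ``run_microsim``
simulates individual trajectories of the same process and is used as an
independent validation oracle: its sample means converge to the cohort
expectations, and the two are compared within Monte-Carlo standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionModel",
    "RewardSchedule",
    "CohortTrace",
    "MicrosimResult",
    "ValidationReport",
    "ModelValidationError",
    "normalize_distribution",
    "validate_model",
    "run_cohort",
    "run_microsim",
]

#: absolute tolerance on transition row sums after normalization
ROW_SUM_TOL = 1e-12
#: config-supplied probability vectors may be off by this much before it is an error
CONFIG_SUM_TOL = 1e-6


class ModelValidationError(ValueError):
    """Raised when a model, distribution or parameter set fails validation."""


def normalize_distribution(probs: Mapping[str, float] | Sequence[float],
                           name: str = "distribution") -> np.ndarray:
    """Check a probability vector and renormalize tiny numeric drift.

    Vectors whose sum deviates from 1 by more than ``CONFIG_SUM_TOL`` are an
    error (they are not silently renormalized); smaller drift — printed-table
    rounding, floating-point accumulation — is rescaled so the row sum is
    exact to machine precision.
    """
    if isinstance(probs, Mapping):
        values = np.asarray(list(probs.values()), dtype=float)
    else:
        values = np.asarray(probs, dtype=float)
    if np.any(values < 0):
        raise ModelValidationError(f"{name}: negative probability {values.min():g}")
    total = values.sum()
    if abs(total - 1.0) > CONFIG_SUM_TOL:
        raise ModelValidationError(
            f"{name}: probabilities sum to {total:.8f}, not 1 (tolerance {CONFIG_SUM_TOL:g})")
    return values / total


@dataclass(frozen=True)
class TransitionModel:
    """State space and per-cycle transition law of one Markov model.

    Parameters
    ----------
    states : ordered state names (unique).
    absorbing : names of absorbing states (e.g. ``"dead"``); their rows must
        be self-loops with probability 1.
    transition : callable ``(cycle_index, state) -> {state: prob}``.  The
        cycle index is 0-based; cycle dependence encodes e.g. screening
        schedules.
    n_cycles : number of cycles the model runs for.
    cycle_length_label : ``"year"`` or ``"month"`` (documentation only).
    """

    states: tuple[str, ...]
    absorbing: frozenset[str]
    transition: Callable[[int, str], Mapping[str, float]]
    n_cycles: int
    cycle_length_label: str = "year"

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ModelValidationError("state names must be unique")
        unknown = self.absorbing - set(self.states)
        if unknown:
            raise ModelValidationError(f"absorbing states not in state list: {sorted(unknown)}")
        if self.n_cycles < 1:
            raise ModelValidationError("n_cycles must be >= 1")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def matrices(self) -> np.ndarray:
        """Compile the transition law into an ``(n_cycles, S, S)`` array."""
        S = self.n_states
        P = np.zeros((self.n_cycles, S, S))
        pos = {s: i for i, s in enumerate(self.states)}
        for t in range(self.n_cycles):
            for i, s in enumerate(self.states):
                row = self.transition(t, s)
                for dest, p in row.items():
                    P[t, i, pos[dest]] = p
        return P


@dataclass(frozen=True)
class RewardSchedule:
    """Per-state / per-transition rewards on named channels.

    ``state_rewards(cycle, state)`` returns the per-cycle reward earned for
    *ending* a cycle in ``state``; ``transition_rewards(cycle, src, dest)``
    returns optional one-off rewards per unit of flow taking that transition
    in that cycle (used for treatment disutility and cost in the year of
    diagnosis, event costs in the month of death, ...).

    Channels are independent: evaluating one never alters another.  The
    utility channel is special only in that transitions into absorbing states
    additionally credit ``death_cycle_fraction`` of the source state's utility
    reward for the cycle of death.
    """

    channels: tuple[str, ...]
    state_rewards: Callable[[int, str], Mapping[str, float]]
    transition_rewards: Callable[[int, str, str], Mapping[str, float]] | None = None
    death_cycle_fraction: float = 0.5
    utility_channel: str = "utility"

    def __post_init__(self) -> None:
        if not 0.0 <= self.death_cycle_fraction <= 1.0:
            raise ModelValidationError("death_cycle_fraction must lie in [0, 1]")

    def compile(self, model: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
        """Compile rewards against a model.

        Returns ``(R_state, R_trans)`` with shapes ``(T, S, C)`` and
        ``(T, S, S, C)``.  The death-cycle utility credit is folded into
        ``R_trans`` on live->absorbing transitions.
        """
        T, S, C = model.n_cycles, model.n_states, len(self.channels)
        cpos = {c: k for k, c in enumerate(self.channels)}
        R_state = np.zeros((T, S, C))
        R_trans = np.zeros((T, S, S, C))
        for t in range(T):
            for i, s in enumerate(model.states):
                for ch, v in self.state_rewards(t, s).items():
                    R_state[t, i, cpos[ch]] = v
        if self.transition_rewards is not None:
            for t in range(T):
                for i, s in enumerate(model.states):
                    for j, d in enumerate(model.states):
                        rw = self.transition_rewards(t, s, d)
                        if rw:
                            for ch, v in rw.items():
                                R_trans[t, i, j, cpos[ch]] += v
        if self.utility_channel in cpos and self.death_cycle_fraction > 0:
            k = cpos[self.utility_channel]
            for t in range(T):
                for i, s in enumerate(model.states):
                    if s in model.absorbing:
                        continue
                    u_src = R_state[t, i, k]
                    for j, d in enumerate(model.states):
                        if d in model.absorbing and d != s:
                            R_trans[t, i, j, k] += self.death_cycle_fraction * u_src
        return R_state, R_trans


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...]

    def raise_if_failed(self) -> None:
        if not self.ok:
            raise ModelValidationError("; ".join(self.violations))


def validate_model(model: TransitionModel,
                   initial: Mapping[str, float] | None = None,
                   tol: float = ROW_SUM_TOL) -> ValidationReport:
    """Structural checks: row sums, negative probabilities, absorbing states.

    If an initial distribution is given, states unreachable from its support
    are also reported.  This is a reporting operation — callers decide whether
    to abort (``report.raise_if_failed()``).
    """
    violations: list[str] = []
    pos = {s: i for i, s in enumerate(model.states)}
    P = np.zeros((model.n_cycles, model.n_states, model.n_states))
    for t in range(model.n_cycles):
        for s in model.states:
            row = model.transition(t, s)
            unknown = set(row) - set(model.states)
            if unknown:
                violations.append(f"cycle {t}, state {s!r}: transitions to unknown states {sorted(unknown)}")
                continue
            for d, p in row.items():
                if p < 0:
                    violations.append(f"cycle {t}, state {s!r}: negative probability {p:g} to {d!r}")
                P[t, pos[s], pos[d]] = p
            rs = sum(row.values())
            if abs(rs - 1.0) > tol:
                violations.append(f"cycle {t}, state {s!r}: row-sum {rs:.15f} != 1")
    for s in model.absorbing:
        i = pos[s]
        for t in range(model.n_cycles):
            if abs(P[t, i, i] - 1.0) > tol or P[t, i].sum() - P[t, i, i] > tol:
                violations.append(f"state {s!r}: absorbing state leaves itself at cycle {t}")
                break
    if initial is not None:
        reach = {s for s, p in initial.items() if p > 0}
        frontier = set(reach)
        adj = (P.sum(axis=0) > 0)
        while frontier:
            nxt = set()
            for s in frontier:
                for j, linked in enumerate(adj[pos[s]]):
                    if linked and model.states[j] not in reach:
                        reach.add(model.states[j])
                        nxt.add(model.states[j])
            frontier = nxt
        for s in model.states:
            if s not in reach:
                violations.append(f"state {s!r}: unreachable from initial distribution")
    return ValidationReport(ok=not violations, violations=tuple(violations))


@dataclass
class CohortTrace:
    """Expected state occupancy per cycle plus cumulative channel totals.

    ``occupancy[0]`` is the initial distribution; row ``t`` is the expected
    occupancy after ``t`` cycles.  ``cumulative[t]`` holds the running channel
    totals through cycle ``t`` (row 0 is zero).  ``per_person`` are the final
    per-person expectations per channel.
    """

    states: tuple[str, ...]
    channels: tuple[str, ...]
    occupancy: np.ndarray          # (n_cycles+1, S)
    cumulative: np.ndarray         # (n_cycles+1, C)
    per_person: dict[str, float] = field(default_factory=dict)

    def occupancy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy, columns=list(self.states)).rename_axis("cycle")

    def to_frame(self) -> pd.DataFrame:
        occ = self.occupancy_frame()
        cum = pd.DataFrame(self.cumulative, columns=[f"cum_{c}" for c in self.channels])
        return pd.concat([occ, cum.set_index(occ.index)], axis=1)

    def to_csv(self, path) -> None:
        """One row per cycle, one column per state and per channel total."""
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class MicrosimResult:
    """Sample means/standard errors from an individual-level simulation."""

    n_individuals: int
    seed: int
    channels: tuple[str, ...]
    means: dict[str, float]
    standard_errors: dict[str, float]
    terminal_counts: dict[str, int]

    def z_scores(self, expected: Mapping[str, float]) -> dict[str, float]:
        """(sample mean - expectation) / SE per channel; inf-safe for SE=0."""
        out = {}
        for ch in self.channels:
            se = self.standard_errors[ch]
            diff = self.means[ch] - expected[ch]
            out[ch] = 0.0 if (se == 0 and abs(diff) < 1e-9) else diff / se if se > 0 else np.inf
        return out


def _check_initial(model: TransitionModel, initial: Mapping[str, float]) -> np.ndarray:
    unknown = set(initial) - set(model.states)
    if unknown:
        raise ModelValidationError(f"initial: unknown states {sorted(unknown)}")
    x0 = np.zeros(model.n_states)
    for s, p in initial.items():
        if p < 0:
            raise ModelValidationError(f"initial: negative probability for {s!r}")
        x0[model.index(s)] = p
    if abs(x0.sum() - 1.0) > 1e-9:
        raise ModelValidationError(f"initial: probabilities sum to {x0.sum():.12f}, not 1")
    return x0


def run_cohort(model: TransitionModel,
               rewards: RewardSchedule,
               initial: Mapping[str, float],
               discount_rate: float = 0.0) -> CohortTrace:
    """Propagate the cohort by expectation and accumulate channel rewards.

    ``discount_rate`` is a per-cycle discount applied to cycle rewards
    (default 0; the shipped analyses apply none).
    """
    validate_model(model).raise_if_failed()
    x = _check_initial(model, initial)
    P = model.matrices()
    R_state, R_trans = rewards.compile(model)
    T, S, C = model.n_cycles, model.n_states, len(rewards.channels)
    occupancy = np.zeros((T + 1, S))
    cumulative = np.zeros((T + 1, C))
    occupancy[0] = x
    for t in range(T):
        flows = x[:, None] * P[t]                       # (S, S)
        x_next = flows.sum(axis=0)
        cycle_reward = (flows[:, :, None] * R_trans[t]).sum(axis=(0, 1))
        cycle_reward += x_next @ R_state[t]
        cycle_reward *= (1.0 + discount_rate) ** -(t + 1)
        occupancy[t + 1] = x_next
        cumulative[t + 1] = cumulative[t] + cycle_reward
        x = x_next
    per_person = {c: float(cumulative[-1, k]) for k, c in enumerate(rewards.channels)}
    return CohortTrace(states=model.states, channels=rewards.channels,
                       occupancy=occupancy, cumulative=cumulative, per_person=per_person)


def run_microsim(model: TransitionModel,
                 rewards: RewardSchedule,
                 initial: Mapping[str, float],
                 n_individuals: int,
                 seed: int) -> MicrosimResult:
    """Simulate independent individual trajectories of the same process.

    Deterministic given ``seed``.  Sample means estimate the cohort
    expectations of :func:`run_cohort`; standard error = sample SD / sqrt(n).
    """
    if n_individuals < 1:
        raise ModelValidationError("n_individuals must be >= 1")
    validate_model(model).raise_if_failed()
    x0 = _check_initial(model, initial)
    rng = np.random.default_rng(seed)
    P = model.matrices()
    R_state, R_trans = rewards.compile(model)
    T, S, C = model.n_cycles, model.n_states, len(rewards.channels)
    cur = rng.choice(S, size=n_individuals, p=x0)
    totals = np.zeros((n_individuals, C))
    for t in range(T):
        nxt = np.empty_like(cur)
        for i in range(S):
            mask = cur == i
            m = int(mask.sum())
            if m == 0:
                continue
            row = P[t, i]
            nz = np.flatnonzero(row)
            if len(nz) == 1:
                nxt[mask] = nz[0]
            else:
                nxt[mask] = rng.choice(S, size=m, p=row)
            totals[mask] += R_trans[t, i, nxt[mask]]
        totals += R_state[t, nxt]
        cur = nxt
    means = totals.mean(axis=0)
    sds = totals.std(axis=0, ddof=1) if n_individuals > 1 else np.zeros(C)
    ses = sds / np.sqrt(n_individuals)
    counts = np.bincount(cur, minlength=S)
    return MicrosimResult(
        n_individuals=n_individuals, seed=seed, channels=rewards.channels,
        means={c: float(means[k]) for k, c in enumerate(rewards.channels)},
        standard_errors={c: float(ses[k]) for k, c in enumerate(rewards.channels)},
        terminal_counts={s: int(counts[i]) for i, s in enumerate(model.states)},
    )
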