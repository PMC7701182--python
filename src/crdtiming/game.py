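"""Exact mechanics of the CRD with timing uncertainty.

The ending round M of a game is ``m0 + G`` with ``G ~ Geometric0(w)``:
rounds ``1..m0`` are always played, then after round ``m0`` and after every
later round the game terminates with probability ``w``, so

    P(M = m0 + k) = w * (1 - w)**k,   k = 0, 1, 2, ...
    E[M] = m0 + (1 - w) / w.

Because all five model strategies are deterministic with one-round memory,
a group's trace is eventually constant (target reached, or every action 0
forever after).  The round from which nothing changes — ``static_round`` —
lets expectations over the unbounded geometric tail be taken analytically:
the tail mass ``(1 - w)**(M* - m0)`` multiplies the frozen state, never a
truncated approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import ConfigError, GameConfig
from .strategies import StrategyProfile, decide


class ContractViolationError(RuntimeError):
    """A strategy emitted an action outside the game's action set."""


@dataclass(frozen=True)
class TerminationDistribution:
    """Distribution of the ending round: explicit masses plus analytic tail.

    ``rounds[i]`` carries mass ``probs[i]`` for rounds ``m0 .. tail_round-1``;
    ``tail_mass = (1-w)**(tail_round - m0)`` aggregates every ending round
    ``>= tail_round`` (where, for the engine's use, play is provably static).
    """

    m0: int
    w: float
    rounds: tuple[int, ...]
    probs: tuple[float, ...]
    tail_round: int
    tail_mass: float

    def pmf(self, m: int) -> float:
        """Exact P(M = m) for any round (ignores the tail aggregation)."""
        if m < self.m0:
            return 0.0
        return self.w * (1.0 - self.w) ** (m - self.m0)

    def total_mass(self) -> float:
        return float(np.sum(self.probs) + self.tail_mass)

    def mean(self) -> float:
        """Mean ending round, with the tail contribution taken in closed form.

        Conditional on not ending before ``tail_round``, the remaining length
        is again geometric (memorylessness), so the tail contributes
        ``tail_mass * (tail_round + (1-w)/w)``.
        """
        explicit = float(np.dot(self.rounds, self.probs))
        tail_mean = self.tail_round + (1.0 - self.w) / self.w
        return explicit + self.tail_mass * tail_mean

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw realized ending rounds."""
        g = rng.geometric(self.w, size=size)  # >= 1
        return self.m0 + g - 1


def termination_distribution(
    m0: int, w: float, tail_round: int | None = None
) -> TerminationDistribution:
    """Ending-round distribution with the mass beyond ``tail_round`` aggregated.

    ``tail_round`` defaults to ``m0 + 60``, far past the static round of any
    standard configuration; callers doing exact expectations pass their own
    static round.
    """
    if m0 < 1:
        raise ConfigError(f"m0 must be >= 1, got {m0}")
    if not 0.0 < w <= 1.0:
        raise ConfigError(f"w must be in (0, 1], got {w}")
    if tail_round is None:
        tail_round = m0 + 60
    tail_round = max(int(tail_round), m0)
    ks = np.arange(tail_round - m0)
    probs = w * (1.0 - w) ** ks
    tail_mass = (1.0 - w) ** (tail_round - m0)
    return TerminationDistribution(
        m0=m0,
        w=w,
        rounds=tuple(range(m0, tail_round)),
        probs=tuple(float(p) for p in probs),
        tail_round=tail_round,
        tail_mass=float(tail_mass),
    )


def expected_rounds(m0: int, w: float) -> float:
    """Mean game length m0 + (1-w)/w; equals 10 for all shipped presets."""
    if m0 < 1:
        raise ConfigError(f"m0 must be >= 1, got {m0}")
    if not 0.0 < w <= 1.0:
        raise ConfigError(f"w must be in (0, 1], got {w}")
    return m0 + (1.0 - w) / w


@dataclass(frozen=True)
class GameTrace:
    """Deterministic round-by-round record of one group's play.

    ``actions`` is the (player x round) contribution matrix; ``cum_totals``
    the cumulative group total after each round; ``player_cum`` each player's
    cumulative contribution C_i(t); ``success_round`` the first round at which
    the cumulative total reaches the threshold (None if never within the
    horizon).
    """

    actions: np.ndarray
    group_totals: np.ndarray
    cum_totals: np.ndarray
    player_cum: np.ndarray
    success_round: int | None

    @property
    def horizon(self) -> int:
        return self.actions.shape[1]

    def contributions_at(self, m: int) -> np.ndarray:
        """Per-player cumulative contribution C_i(m) after round m."""
        return self.player_cum[:, m - 1]


@dataclass(frozen=True)
class GameOutcome:
    """Expectations of one group's play over the ending-round distribution."""

    success_probability: float
    expected_payoffs: np.ndarray
    expected_contributions: np.ndarray
    expected_rounds: float


def play_group(
    profiles: Sequence[StrategyProfile], config: GameConfig, horizon: int
) -> GameTrace:
    """Play a group of deterministic strategies for ``horizon`` rounds.

    Each round every player's rule is evaluated on the public history (the
    others' previous-round total and the cumulative group total through the
    previous round), clipped to the remaining endowment.  Once the cumulative
    total reaches the threshold all subsequent actions are 0.
    """
    n = len(profiles)
    if n != config.n_players:
        raise ConfigError(
            f"expected {config.n_players} profiles, got {n}"
        )
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")

    actions = np.zeros((n, horizon), dtype=np.int64)
    remaining = np.full(n, config.endowment, dtype=np.int64)
    prev = np.zeros(n, dtype=np.int64)
    cum = 0
    success_round: int | None = None
    action_set = set(config.actions)

    for t in range(1, horizon + 1):
        prev_sum = int(prev.sum())
        for i, profile in enumerate(profiles):
            a = decide(
                profile,
                t,
                prev_sum - int(prev[i]),
                cum,
                int(remaining[i]),
                config,
            )
            if a not in action_set:
                raise ContractViolationError(
                    f"player {i} round {t}: action {a} not in {config.actions}"
                )
            actions[i, t - 1] = a
        prev = actions[:, t - 1]
        remaining -= prev
        cum += int(prev.sum())
        if success_round is None and cum >= config.threshold:
            success_round = t

    group_totals = actions.sum(axis=0)
    return GameTrace(
        actions=actions,
        group_totals=group_totals,
        cum_totals=np.cumsum(group_totals),
        player_cum=np.cumsum(actions, axis=1),
        success_round=success_round,
    )


def static_round(profiles: Sequence[StrategyProfile], config: GameConfig) -> int:
    """Smallest round M* from which the trace is provably constant.

    Reached when the target is met (all rules return 0 thereafter) or when
    two consecutive rounds are all-zero: with one-round-memory deterministic
    rules and unchanged endowments, an all-zero round following an all-zero
    round is a fixed point.  Total contributions are bounded by N*E and every
    non-static round adds at least the smallest positive action every other
    round, which bounds the search.
    """
    bound = 2 * (config.n_players * config.endowment // config.min_positive_action) + 4
    trace = play_group(profiles, config, bound)
    if trace.success_round is not None:
        return trace.success_round
    zero = ~trace.group_totals.astype(bool)
    for t in range(bound - 1):
        if zero[t] and zero[t + 1]:
            return t + 1  # 1-based round index
    raise RuntimeError(
        "trace did not become static within the theoretical bound"
    )  # pragma: no cover - unreachable for valid rules


def expected_outcome(
    profiles: Sequence[StrategyProfile], config: GameConfig
) -> GameOutcome:
    """Exact expectations over the ending-round distribution.

    The payoff of player i at ending round M is ``E - C_i(M)`` when the
    cumulative total at M has reached the threshold, and
    ``(1 - r) * (E - C_i(M))`` otherwise (the disaster is applied in
    expectation).  The expectation sums the explicit geometric masses for
    rounds ``m0 .. M*-1`` and multiplies the aggregated tail mass by the
    frozen state at the static round M*.
    """
    m_star = static_round(profiles, config)
    horizon = max(m_star, config.m0)
    trace = play_group(profiles, config, horizon)
    td = termination_distribution(config.m0, config.w, tail_round=max(m_star, config.m0))

    e = float(config.endowment)
    succ_p = 0.0
    pay = np.zeros(config.n_players)
    contrib = np.zeros(config.n_players)

    ends = list(zip(td.rounds, td.probs)) + [(td.tail_round, td.tail_mass)]
    for m, p in ends:
        if p == 0.0:
            continue
        c = trace.contributions_at(min(m, horizon)).astype(float)
        success = bool(trace.cum_totals[min(m, horizon) - 1] >= config.threshold)
        payoff = e - c if success else (1.0 - config.risk) * (e - c)
        succ_p += p * success
        pay += p * payoff
        contrib += p * c

    return GameOutcome(
        success_probability=float(succ_p),
        expected_payoffs=pay,
        expected_contributions=contrib,
        expected_rounds=expected_rounds(config.m0, config.w),
    )
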