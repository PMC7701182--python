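"""The five behavioral strategies of the evolutionary model.

Three unconditional rules — always-0, always-2, always-4 — contribute a fixed
amount every round.  Two conditional rules react to what the *other* group
members contributed in the previous round (one-round memory, public
information):

* ``RECIPROCAL`` contributes generously (``high_action``) as long as the
  others contributed at least ``theta`` EMU in the previous round, and
  ``low_action`` otherwise.  Its round-1 move is ``first_action``
  (optimistic opener by default).
* ``COMPENSATOR`` mirrors this: it contributes ``high_action`` precisely when
  the others did *not* reach ``theta`` (round 1 counts as "no previous
  contribution", so it opens generously too).

Every strategy stops contributing once the collective target has been
reached, and a request exceeding the remaining endowment is clipped to the
largest feasible action.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .config import ConfigError, GameConfig


class StrategyKind(str, Enum):
    ALWAYS0 = "always-0"
    ALWAYS2 = "always-2"
    ALWAYS4 = "always-4"
    COMPENSATOR = "compensator"
    RECIPROCAL = "reciprocal"


#: Canonical ordering used for vectors indexed by strategy.
STRATEGY_ORDER: tuple[StrategyKind, ...] = (
    StrategyKind.ALWAYS0,
    StrategyKind.ALWAYS2,
    StrategyKind.ALWAYS4,
    StrategyKind.COMPENSATOR,
    StrategyKind.RECIPROCAL,
)

_FIXED_ACTION = {
    StrategyKind.ALWAYS0: 0,
    StrategyKind.ALWAYS2: 2,
    StrategyKind.ALWAYS4: 4,
}

#: Strategies that contribute toward the target (everything but always-0).
CONTRIBUTING_KINDS = frozenset(
    k for k in STRATEGY_ORDER if k is not StrategyKind.ALWAYS0
)


@dataclass(frozen=True)
class StrategyProfile:
    """One behavioral rule with its conditional-rule parameters.

    ``theta`` is the others'-previous-round-total threshold (EMU) used by the
    conditional kinds; ``None`` resolves to the default ``2 * (N - 1)``,
    i.e. the others averaging at least the low positive action.  Unconditional
    kinds ignore ``theta``/``first_action``/``high_action``/``low_action``.
    """

    kind: StrategyKind
    theta: float | None = None
    first_action: int | None = None
    high_action: int = 4
    low_action: int = 0

    def resolved(self, config: GameConfig) -> "StrategyProfile":
        """Return a copy with all ``None`` parameters made explicit."""
        theta = self.theta if self.theta is not None else default_theta(config)
        first = self.first_action if self.first_action is not None else self.high_action
        return replace(self, theta=theta, first_action=first)


def default_theta(config: GameConfig) -> float:
    """Others' previous-round total counting as "the group contributed".

    ``2 * (N - 1)`` EMU: the co-players averaged at least the low positive
    action in the previous round.
    """
    return 2.0 * (config.n_players - 1)


def default_profiles(config: GameConfig) -> dict[StrategyKind, StrategyProfile]:
    """The five model strategies with their default parameterization."""
    theta = default_theta(config)
    return {
        StrategyKind.ALWAYS0: StrategyProfile(StrategyKind.ALWAYS0),
        StrategyKind.ALWAYS2: StrategyProfile(StrategyKind.ALWAYS2),
        StrategyKind.ALWAYS4: StrategyProfile(StrategyKind.ALWAYS4),
        StrategyKind.COMPENSATOR: StrategyProfile(
            StrategyKind.COMPENSATOR, theta=theta, high_action=4, low_action=0
        ),
        StrategyKind.RECIPROCAL: StrategyProfile(
            StrategyKind.RECIPROCAL,
            theta=theta,
            first_action=4,
            high_action=4,
            low_action=0,
        ),
    }


def clip_to_remaining(action: int, remaining: int, config: GameConfig) -> int:
    """Largest feasible action <= min(action, remaining) from the action set."""
    if action <= remaining:
        return action
    return max(a for a in config.actions if a <= remaining)


def decide(
    profile: StrategyProfile,
    round_index: int,
    others_prev_total: float,
    cum_group_total: float,
    remaining: int,
    config: GameConfig,
) -> int:
    """Evaluate one strategy's rule on the public history.

    Parameters
    ----------
    round_index : int
        1-based round number.
    others_prev_total : float
        Sum of the other N-1 players' contributions in the previous round
        (0 for round 1).
    cum_group_total : float
        Cumulative group contribution through the previous round.
    remaining : int
        The player's remaining endowment (EMU).

    Returns the contribution in EMU, already clipped to the remaining
    endowment.  Returns 0 whenever the collective target has been reached.
    """
    if round_index < 1:
        raise ValueError(f"round_index must be >= 1, got {round_index}")
    if cum_group_total >= config.threshold:
        return 0

    kind = profile.kind
    if kind in _FIXED_ACTION:
        raw = _FIXED_ACTION[kind]
    elif kind is StrategyKind.RECIPROCAL:
        p = profile.resolved(config)
        if round_index == 1:
            raw = p.first_action
        else:
            raw = p.high_action if others_prev_total >= p.theta else p.low_action
    elif kind is StrategyKind.COMPENSATOR:
        p = profile.resolved(config)
        # round 1 counts as "no previous contribution"
        x = 0.0 if round_index == 1 else others_prev_total
        raw = p.high_action if x < p.theta else p.low_action
    else:
        raise ConfigError(f"unknown strategy kind: {kind!r}")

    if raw not in config.actions:
        raise ConfigError(
            f"strategy {kind.value} emitted action {raw} outside the action set "
            f"{config.actions}"
        )
    return clip_to_remaining(raw, remaining, config)
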