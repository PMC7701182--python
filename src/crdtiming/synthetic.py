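"""Seeded generator of experiment-shaped CRD datasets with known ground truth.

Each generated cohort emulates one treatment of the behavioral experiment:
groups of six players, per-round actions in {0, 2, 4} capped by the remaining
endowment of 40 EMU, and one realized game length per group drawn from the
treatment's termination distribution (a single dice sequence per group, as in
the laboratory).  Player behaviors are drawn from a configurable mixture of
the five model strategies, with an optional trembling-hand noise: with
probability ``noise_eps`` a player's intended action is replaced by a uniform
draw from the action set (then clipped to the remaining endowment, so actions
stay feasible).

The generator is a test harness with planted structure, not a behavioral
model of real participants; the ground-truth sidecar records every player's
assigned strategy and every group's realized length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .analysis import ExperimentTable
from .config import ConfigError, GameConfig, PRESETS
from .game import termination_distribution
from .strategies import (
    STRATEGY_ORDER,
    StrategyKind,
    StrategyProfile,
    clip_to_remaining,
    decide,
    default_profiles,
)


@dataclass
class CohortSpec:
    """One synthetic cohort: treatment, size, strategy mixture, noise, seed."""

    treatment: str
    n_groups: int
    mixture: Mapping[StrategyKind, float]
    noise_eps: float = 0.0
    seed: int | None = None
    profile_overrides: Mapping[StrategyKind, StrategyProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ConfigError(f"n_groups must be >= 1, got {self.n_groups}")
        if not 0.0 <= self.noise_eps <= 1.0:
            raise ConfigError(f"noise_eps must be in [0, 1], got {self.noise_eps}")
        self.mixture = {StrategyKind(k): float(v) for k, v in self.mixture.items()}
        total = sum(self.mixture.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ConfigError(f"mixture must sum to 1, got {total}")
        if any(v < 0 for v in self.mixture.values()):
            raise ConfigError("mixture probabilities must be >= 0")


#: Classifier-style label for each planted strategy kind.
PROFILE_LABEL_OF_KIND = {
    StrategyKind.ALWAYS0: "unconditional-0",
    StrategyKind.ALWAYS2: "unconditional-2",
    StrategyKind.ALWAYS4: "unconditional-4",
    StrategyKind.RECIPROCAL: "reciprocal-like",
    StrategyKind.COMPENSATOR: "compensator-like",
}


def effective_profile(
    kind: StrategyKind,
    pre_success_actions: list[int],
    config: GameConfig | None = None,
) -> str:
    """The planted rule as expressed in the observed game.

    A conditional player whose context never crossed theta emits exactly the
    action sequence of an unconditional rule (including endowment clipping)
    before the target is reached, and is behaviorally indistinguishable from
    it within that game; the effective profile records that identifiability
    limit, so recovery can be judged against what the data can reveal.
    """
    config = config or GameConfig()
    label = PROFILE_LABEL_OF_KIND[kind]
    if label.startswith("unconditional") or not pre_success_actions:
        return label
    for k in config.actions:
        remaining = config.endowment
        for a in pre_success_actions:
            if a != clip_to_remaining(k, remaining, config):
                break
            remaining -= a
        else:
            return f"unconditional-{k}"
    return label


def generate(
    spec: CohortSpec, config: GameConfig | None = None
) -> tuple[ExperimentTable, dict]:
    """Generate one cohort and its ground truth.

    Returns the validated :class:`ExperimentTable` and a JSON-serializable
    sidecar with each group's realized length and assigned strategies.
    Byte-identical output for identical seeds.
    """
    config = config or PRESETS[spec.treatment]
    rng = np.random.default_rng(spec.seed)
    td = termination_distribution(config.m0, config.w)
    profiles = default_profiles(config)
    profiles.update(spec.profile_overrides)

    kinds = [k for k in STRATEGY_ORDER if spec.mixture.get(k, 0.0) > 0]
    probs = np.array([spec.mixture[k] for k in kinds])

    rows = []
    truth_groups = []
    n = config.n_players
    for g in range(spec.n_groups):
        gid = f"{spec.treatment}-g{g:03d}"
        length = int(td.sample(rng))
        assigned = [kinds[i] for i in rng.choice(len(kinds), size=n, p=probs)]
        group_profiles = [profiles[k] for k in assigned]

        remaining = np.full(n, config.endowment, dtype=np.int64)
        prev = np.zeros(n, dtype=np.int64)
        cum = 0
        pre_success_actions: list[list[int]] = [[] for _ in range(n)]
        for t in range(1, length + 1):
            prev_sum = int(prev.sum())
            acts = np.zeros(n, dtype=np.int64)
            for i in range(n):
                a = decide(
                    group_profiles[i],
                    t,
                    prev_sum - int(prev[i]),
                    cum,
                    int(remaining[i]),
                    config,
                )
                if spec.noise_eps > 0 and rng.random() < spec.noise_eps:
                    a = clip_to_remaining(
                        int(rng.choice(config.actions)), int(remaining[i]), config
                    )
                acts[i] = a
                if cum < config.threshold:
                    pre_success_actions[i].append(int(a))
                rows.append(
                    {
                        "treatment": spec.treatment,
                        "group_id": gid,
                        "player_id": f"{gid}-p{i}",
                        "round": t,
                        "action": int(a),
                    }
                )
            prev = acts
            remaining -= acts
            cum += int(acts.sum())

        truth_groups.append(
            {
                "group_id": gid,
                "treatment": spec.treatment,
                "length": length,
                "strategies": [k.value for k in assigned],
                "effective_profiles": [
                    effective_profile(k, pre_success_actions[i], config)
                    for i, k in enumerate(assigned)
                ],
            }
        )

    table = ExperimentTable(pd.DataFrame(rows))
    truth = {
        "spec": {
            "treatment": spec.treatment,
            "n_groups": spec.n_groups,
            "mixture": {k.value: v for k, v in spec.mixture.items()},
            "noise_eps": spec.noise_eps,
            "seed": spec.seed,
        },
        "groups": truth_groups,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Hand-built fixtures for analysis edge cases
# ---------------------------------------------------------------------------

def _rows(treatment: str, gid: str, player_actions: list[list[int]]):
    out = []
    for i, acts in enumerate(player_actions):
        for t, a in enumerate(acts, start=1):
            out.append(
                {
                    "treatment": treatment,
                    "group_id": gid,
                    "player_id": f"{gid}-p{i}",
                    "round": t,
                    "action": a,
                }
            )
    return out


def fixture_suite() -> dict[str, pd.DataFrame]:
    """Deterministic hand-built tables covering the analysis edge cases.

    * ``nu_all_fair`` — every player gives 2 in all 10 NU rounds (C = F).
    * ``planted_two_all2`` — exactly two players give 2 every round; the
      group still succeeds.
    * ``hu_early`` — 6-round HU games front-loaded into the first half.
    * ``polarized`` — half the players give everything, half nothing.
    * ``short_hu`` — an HU group that ended at the earliest round (6).
    """
    fixtures: dict[str, pd.DataFrame] = {}

    fixtures["nu_all_fair"] = pd.DataFrame(
        _rows("NU", "nu-f0", [[2] * 10] * 6) + _rows("NU", "nu-f1", [[2] * 10] * 6)
    )

    # two all-2 players; the other four alternate 4/2 (24 extra EMU over 10
    # rounds) so the group total is 136 >= 120 and nobody is constant at 2.
    alt = [4, 2] * 5
    fixtures["planted_two_all2"] = pd.DataFrame(
        _rows("NU", "nu-c0", [[2] * 10, [2] * 10, alt, alt, alt, alt])
    )

    # HU games of 6 rounds: all contributions in rounds 1-3 (first half).
    early = [4, 4, 4, 0, 0, 0]
    late = [0, 0, 0, 4, 4, 4]
    fixtures["hu_early"] = pd.DataFrame(
        _rows("HU", "hu-e0", [early] * 6) + _rows("HU", "hu-e1", [early] * 5 + [late])
    )

    fixtures["polarized"] = pd.DataFrame(
        _rows("NU", "nu-p0", [[4] * 10] * 3 + [[0] * 10] * 3)
    )

    fixtures["short_hu"] = pd.DataFrame(
        _rows("HU", "hu-s0", [[4] * 6] * 6)
    )
    return fixtures
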