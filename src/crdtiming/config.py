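"""Game-level configuration for the collective risk dilemma (CRD).

A CRD group of ``n_players`` plays a multi-round threshold public goods game.
Each player starts with an endowment ``endowment`` (in EMU, experimental
monetary units) and per round contributes one of the amounts in ``actions``.
If the group's cumulative contribution reaches ``threshold`` before the game
ends, every player keeps what remains of their endowment; otherwise each loses
the remainder with probability ``risk``.

Timing uncertainty is parameterized by ``m0`` and ``w``: rounds ``1..m0`` are
always played, and after round ``m0`` (and after every later round) the game
terminates with probability ``w``.  The realized length is therefore
``m0 + G`` with ``G`` geometric, giving mean length ``m0 + (1 - w) / w``.
The three shipped presets — no (NU), low (LU) and high (HU) uncertainty — all
have mean length 10 rounds.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, replace
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a game or run configuration violates its invariants."""


@dataclass(frozen=True)
class GameConfig:
    """All game-level constants for one treatment.

    Parameters
    ----------
    n_players : int
        Group size N (>= 2).
    endowment : int
        Initial per-player endowment E in EMU.
    actions : tuple of int
        Ordered set of admissible per-round contributions; must contain 0.
    threshold : int
        Collective target tau in EMU.
    risk : float
        Probability r of losing the remaining endowment on collective failure.
    m0 : int
        First round at which the game may end (rounds 1..m0 always played).
    w : float
        Per-check termination probability in (0, 1]; w = 1 gives a
        fixed-length game of exactly m0 rounds.
    """

    n_players: int = 6
    endowment: int = 40
    actions: tuple[int, ...] = (0, 2, 4)
    threshold: int = 120
    risk: float = 0.9
    m0: int = 10
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.n_players < 2:
            raise ConfigError(f"n_players must be >= 2, got {self.n_players}")
        if self.endowment <= 0:
            raise ConfigError(f"endowment must be > 0, got {self.endowment}")
        if self.threshold <= 0:
            raise ConfigError(f"threshold must be > 0, got {self.threshold}")
        if not 0.0 <= self.risk <= 1.0:
            raise ConfigError(f"risk must be in [0, 1], got {self.risk}")
        if self.m0 < 1:
            raise ConfigError(f"m0 must be >= 1, got {self.m0}")
        if not 0.0 < self.w <= 1.0:
            raise ConfigError(f"w must be in (0, 1], got {self.w}")
        acts = tuple(sorted(int(a) for a in self.actions))
        if 0 not in acts or any(a < 0 for a in acts):
            raise ConfigError(
                f"actions must all be >= 0 and include 0, got {self.actions}"
            )
        object.__setattr__(self, "actions", acts)

    @property
    def fair_share(self) -> float:
        """F = E/2, the per-player total that exactly meets the target."""
        return self.endowment / 2

    @property
    def max_action(self) -> int:
        return self.actions[-1]

    @property
    def min_positive_action(self) -> int:
        for a in self.actions:
            if a > 0:
                return a
        raise ConfigError("action set has no positive action")


#: Treatment presets: no / low / high timing uncertainty, all with mean
#: game length m0 + (1-w)/w = 10 rounds.
PRESETS: dict[str, GameConfig] = {
    "NU": GameConfig(m0=10, w=1.0),
    "LU": GameConfig(m0=8, w=1.0 / 3.0),
    "HU": GameConfig(m0=6, w=1.0 / 5.0),
}

TREATMENTS = tuple(PRESETS)

_GAME_KEYS = {
    "n": "n_players",
    "n_players": "n_players",
    "e": "endowment",
    "endowment": "endowment",
    "tau": "threshold",
    "threshold": "threshold",
    "r": "risk",
    "risk": "risk",
    "m0": "m0",
    "w": "w",
    "actions": "actions",
}


def _parse_game_section(items: dict[str, str], base: GameConfig) -> GameConfig:
    kwargs: dict = {}
    for key, raw in items.items():
        canon = _GAME_KEYS.get(key.lower())
        if canon is None:
            raise ConfigError(f"unknown game config key: {key!r}")
        if canon == "actions":
            kwargs[canon] = tuple(int(tok) for tok in raw.replace(",", " ").split())
        elif canon in ("n_players", "endowment", "threshold", "m0"):
            kwargs[canon] = int(raw)
        else:
            kwargs[canon] = _parse_fraction(raw)
    return replace(base, **kwargs)


def _parse_fraction(raw: str) -> float:
    """Parse a float that may be written as a fraction such as ``1/3``."""
    raw = raw.strip()
    if "/" in raw:
        num, den = raw.split("/", 1)
        return float(num) / float(den)
    return float(raw)


def load_config(path: str | Path) -> dict:
    """Read an INI-style run configuration.

    Sections ``[game.NU]``/``[game.LU]``/``[game.HU]`` override the shipped
    presets; ``[strategies]``, ``[population]`` and ``[cohort]`` are returned
    as plain key/value dicts for the corresponding modules to interpret.

    Returns a dict with keys ``games`` (treatment -> GameConfig),
    ``strategies``, ``population`` and ``cohort``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:  # pragma: no cover - parser detail
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc

    games = dict(PRESETS)
    out: dict = {"games": games, "strategies": {}, "population": {}, "cohort": {}}
    for section in parser.sections():
        items = dict(parser.items(section))
        if section.startswith("game."):
            treatment = section.split(".", 1)[1].upper()
            base = games.get(treatment, GameConfig())
            games[treatment] = _parse_game_section(items, base)
        elif section in ("strategies", "population", "cohort"):
            out[section] = items
        else:
            raise ConfigError(f"unknown config section: [{section}]")
    return out
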