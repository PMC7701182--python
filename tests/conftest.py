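import pandas as pd
import pytest

from crdtiming.config import PRESETS
from crdtiming.strategies import StrategyKind, default_profiles


@pytest.fixture(scope="session")
def nu():
    return PRESETS["NU"]


@pytest.fixture(scope="session")
def lu():
    return PRESETS["LU"]


@pytest.fixture(scope="session")
def hu():
    return PRESETS["HU"]


@pytest.fixture(scope="session")
def profiles(nu):
    """Default profiles keyed by kind (theta etc. resolved for N = 6)."""
    return default_profiles(nu)


@pytest.fixture(scope="session")
def group_of(profiles, nu):
    """Factory: a homogeneous group of 6 players of one strategy kind."""

    def _make(kind: StrategyKind):
        return [profiles[kind]] * nu.n_players

    return _make


def canonical_rows(treatment, gid, player_actions):
    """Long-format rows from a per-player action list (tests' table builder)."""
    rows = []
    for i, acts in enumerate(player_actions):
        for t, a in enumerate(acts, start=1):
            rows.append(
                {
                    "treatment": treatment,
                    "group_id": gid,
                    "player_id": f"{gid}-p{i}",
                    "round": t,
                    "action": a,
                }
            )
    return rows


@pytest.fixture()
def make_table():
    def _make(*groups):
        rows = []
        for treatment, gid, player_actions in groups:
            rows.extend(canonical_rows(treatment, gid, player_actions))
        return pd.DataFrame(rows)

    return _make
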