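"""Analysis stages for CRD decision tables (deposited or synthetic).

The canonical table is long format, one decision per row:
``treatment, group_id, player_id, round, action``.  All stages operate on it:

* per-round group mean contributions with t-based 95% CIs,
* fraction of successful groups with Clopper-Pearson intervals,
* fairness classification of per-player totals C against the fair share F,
* first-/second-half contributions against F/2,
* conditional-response tables (focal action vs. the others' previous-round
  total) with a count-weighted linear regression whose slope sign separates
  reciprocal (positive) from compensatory (negative) response,
* per-player behavioral-profile classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import GameConfig, PRESETS
from .strategies import StrategyKind, decide, default_profiles

CANONICAL_COLUMNS = ("treatment", "group_id", "player_id", "round", "action")

#: Template schema map for the study's Dryad deposit
#: (doi:10.5061/dryad.5qfttdz2t).  The deposit's column names are validated
#: on load, not assumed: fill the right-hand sides after downloading, run
#: ``load_table(path, schema_map=DRYAD_SCHEMA_TEMPLATE)`` and the loader will
#: name any column it cannot find.
DRYAD_SCHEMA_TEMPLATE: dict[str, str] = {
    "treatment": "treatment",
    "group_id": "group",
    "player_id": "player",
    "round": "round",
    "action": "action",
}

PROFILE_LABELS = (
    "unconditional-0",
    "unconditional-2",
    "unconditional-4",
    "reciprocal-like",
    "compensator-like",
    "other",
)


class ValidationError(ValueError):
    """A decision table violates the canonical-schema invariants."""


class ExperimentTable:
    """Validated long-format decision records with derived summaries."""

    def __init__(self, df: pd.DataFrame, config_map: Mapping[str, GameConfig] | None = None):
        self.config_map = dict(config_map or PRESETS)
        self.df = self._validate(df)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config_map: Mapping[str, GameConfig] | None = None
    ) -> "ExperimentTable":
        return cls(df, config_map)

    def _validate(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing canonical columns: {missing}")
        df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
        df["round"] = df["round"].astype(int)
        df["action"] = df["action"].astype(int)

        for treatment, sub in df.groupby("treatment", sort=False):
            cfg = self.config_map.get(str(treatment))
            if cfg is None:
                raise ValidationError(f"unknown treatment {treatment!r}")
            bad = sub[~sub["action"].isin(cfg.actions)]
            if len(bad):
                raise ValidationError(
                    f"non-action values {sorted(bad['action'].unique())} in treatment "
                    f"{treatment}; first offending row index {bad.index[0]}"
                )
            totals = sub.groupby(["group_id", "player_id"])["action"].sum()
            over = totals[totals > cfg.endowment]
            if len(over):
                g, p = over.index[0]
                raise ValidationError(
                    f"player {p} of group {g} ({treatment}) contributes "
                    f"{over.iloc[0]} > endowment {cfg.endowment}"
                )
            for gid, grp in sub.groupby("group_id", sort=False):
                lengths = grp.groupby("player_id")["round"].agg(["min", "max", "count"])
                if lengths["max"].nunique() != 1 or lengths["min"].nunique() != 1:
                    raise ValidationError(
                        f"group {gid} ({treatment}): players disagree on realized length"
                    )
                lo, hi, cnt = lengths.iloc[0]
                if lo != 1 or (lengths["count"] != hi).any():
                    raise ValidationError(
                        f"group {gid} ({treatment}): rounds not contiguous from 1"
                    )
        return df.sort_values(["treatment", "group_id", "player_id", "round"]).reset_index(
            drop=True
        )

    # -- derived summaries -------------------------------------------------
    def subset(self, treatment: str) -> pd.DataFrame:
        sub = self.df[self.df["treatment"] == treatment]
        if sub.empty:
            raise ValidationError(f"no rows for treatment {treatment!r}")
        return sub

    def config(self, treatment: str) -> GameConfig:
        return self.config_map[treatment]

    def group_lengths(self, treatment: str) -> pd.Series:
        return self.subset(treatment).groupby("group_id")["round"].max()

    def player_totals(self, treatment: str) -> pd.Series:
        """Per-player total contribution C (EMU)."""
        return self.subset(treatment).groupby(["group_id", "player_id"])["action"].sum()

    def group_success(self, treatment: str) -> pd.Series:
        """Whether each group's cumulative total reached the threshold by its
        realized final round."""
        cfg = self.config(treatment)
        totals = self.subset(treatment).groupby("group_id")["action"].sum()
        return totals >= cfg.threshold

    def _filter_groups(self, treatment: str, successful_only: bool | None) -> pd.DataFrame:
        sub = self.subset(treatment)
        if successful_only is None:
            return sub
        success = self.group_success(treatment)
        keep = success[success == successful_only].index
        return sub[sub["group_id"].isin(keep)]


def load_table(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
    sep: str = ",",
    config_map: Mapping[str, GameConfig] | None = None,
) -> ExperimentTable:
    """Read a delimited decision table and validate it.

    ``schema_map`` maps canonical field names to source column names (for the
    Dryad deposit start from :data:`DRYAD_SCHEMA_TEMPLATE`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"decision table not found: {path}")
    df = pd.read_csv(path, sep=sep)
    if schema_map:
        missing = [src for src in schema_map.values() if src not in df.columns]
        if missing:
            raise ValidationError(
                f"source columns {missing} not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
        df = df.rename(columns={src: canon for canon, src in schema_map.items()})
    return ExperimentTable(df, config_map)


# ---------------------------------------------------------------------------
# Per-round means and success fractions
# ---------------------------------------------------------------------------

def per_round_means(
    table: ExperimentTable, treatment: str, confidence: float = 0.95
) -> pd.DataFrame:
    """Mean group contribution per round with a t-interval over groups.

    Groups whose realized length is shorter than a round drop out of that
    round's average.  With a single group the mean is returned and the CI is
    flagged undefined (NaN).
    """
    sub = table.subset(treatment)
    per_group = (
        sub.groupby(["round", "group_id"])["action"].sum().rename("group_total").reset_index()
    )
    rows = []
    for rnd, grp in per_group.groupby("round"):
        vals = grp["group_total"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sem = vals.std(ddof=1) / math.sqrt(n)
            tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            lo = hi = float("nan")
        rows.append({"round": rnd, "mean": mean, "ci_low": lo, "ci_high": hi, "n_groups": n})
    return pd.DataFrame(rows)


def success_fraction(
    table: ExperimentTable, treatment: str, confidence: float = 0.95
) -> dict:
    """Fraction of successful groups with an exact (Clopper-Pearson) CI."""
    success = table.group_success(treatment)
    n = len(success)
    if n == 0:
        raise ValidationError(f"no groups for treatment {treatment!r}")
    k = int(success.sum())
    lo, hi = proportion_confint(k, n, alpha=1 - confidence, method="beta")
    return {
        "fraction": k / n,
        "n_groups": n,
        "n_successful": k,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


# ---------------------------------------------------------------------------
# Fairness and half-splits
# ---------------------------------------------------------------------------

def fairness_classification(
    table: ExperimentTable, treatment: str, successful_only: bool | None = True
) -> dict:
    """Fractions of players contributing in total less than, exactly, or more
    than the fair share F = E/2 (default: players of successful groups)."""
    cfg = table.config(treatment)
    sub = table._filter_groups(treatment, successful_only)
    if sub.empty:
        raise ValidationError(
            f"no players selected for treatment {treatment!r} "
            f"(successful_only={successful_only})"
        )
    c = sub.groupby(["group_id", "player_id"])["action"].sum()
    f = cfg.fair_share
    n = len(c)
    return {
        "below": float((c < f).sum() / n),
        "equal": float((c == f).sum() / n),
        "above": float((c > f).sum() / n),
        "n_players": n,
    }


def half_split(
    table: ExperimentTable, treatment: str, successful_only: bool | None = True
) -> pd.DataFrame:
    """Per-half fractions of players below / at / above F/2.

    The first half is rounds ``1..m0/2`` (5, 4 and 3 rounds for NU, LU and
    HU); the second half runs from there to the realized end.  Players of
    groups shorter than the first half are excluded and counted in the
    ``n_excluded`` column.
    """
    cfg = table.config(treatment)
    sub = table._filter_groups(treatment, successful_only)
    half = cfg.m0 // 2
    half_f = cfg.fair_share / 2

    lengths = sub.groupby("group_id")["round"].max()
    long_enough = lengths[lengths >= half].index
    excluded = len(lengths) - len(long_enough)
    sub = sub[sub["group_id"].isin(long_enough)]
    if sub.empty:
        raise ValidationError(f"no groups of length >= {half} for {treatment!r}")

    rows = []
    for name, mask in (
        ("first", sub["round"] <= half),
        ("second", sub["round"] > half),
    ):
        c_half = sub[mask].groupby(["group_id", "player_id"])["action"].sum()
        # players with no rows in a half (e.g. game ended at the boundary)
        # contributed 0 in that half
        all_players = sub.groupby(["group_id", "player_id"]).size().index
        c_half = c_half.reindex(all_players, fill_value=0)
        n = len(c_half)
        rows.append(
            {
                "half": name,
                "below": float((c_half < half_f).sum() / n),
                "equal": float((c_half == half_f).sum() / n),
                "above": float((c_half > half_f).sum() / n),
                "n_players": n,
                "n_excluded_groups": excluded,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conditional response and weighted regression
# ---------------------------------------------------------------------------

def _with_context(sub: pd.DataFrame) -> pd.DataFrame:
    """Attach others' previous-round total and previous cumulative total."""
    sub = sub.sort_values(["group_id", "player_id", "round"]).copy()
    group_totals = sub.groupby(["group_id", "round"])["action"].transform("sum")
    sub["group_total"] = group_totals
    sub["others_total"] = sub["group_total"] - sub["action"]

    per_round = (
        sub.groupby(["group_id", "round"])["action"].sum().groupby("group_id").cumsum()
    )
    cum = per_round.rename("cum_total").reset_index()
    sub = sub.merge(cum, on=["group_id", "round"], how="left")

    prev = sub[["group_id", "player_id", "round", "others_total", "cum_total"]].copy()
    prev["round"] += 1
    prev = prev.rename(
        columns={"others_total": "others_prev_total", "cum_total": "cum_prev_total"}
    )
    sub = sub.merge(prev, on=["group_id", "player_id", "round"], how="left")
    sub["others_prev_total"] = sub["others_prev_total"].fillna(0).astype(int)
    sub["cum_prev_total"] = sub["cum_prev_total"].fillna(0).astype(int)
    return sub


@dataclass
class ConditionalTable:
    """Binned conditional response: for each observed others'-previous-round
    total x, the mean focal contribution, observation count and the frequency
    of each action."""

    data: pd.DataFrame  # columns: x, mean, count, freq_<a>...
    treatment: str
    successful_only: bool | None


@dataclass
class RegressionFit:
    """Count-weighted least-squares fit of bin mean on x."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_pvalue: float
    weights: np.ndarray
    n_bins: int


def conditional_table(
    table: ExperimentTable,
    treatment: str,
    successful_only: bool | None = None,
    pre_success_only: bool = False,
) -> ConditionalTable:
    """Mean focal contribution vs. the others' previous-round total.

    Uses all rounds t >= 2 of the selected groups; x is the sum of the other
    N-1 players' actions at t-1.  With ``pre_success_only`` the rounds after
    a group reached the target (where every strategy plays 0) are dropped.
    """
    cfg = table.config(treatment)
    sub = table._filter_groups(treatment, successful_only)
    sub = _with_context(sub)
    obs = sub[sub["round"] >= 2]
    if pre_success_only:
        obs = obs[obs["cum_prev_total"] < cfg.threshold]
    if obs.empty:
        raise ValidationError(f"no rounds >= 2 for treatment {treatment!r}")

    rows = []
    for x, grp in obs.groupby("others_prev_total"):
        row = {"x": int(x), "mean": float(grp["action"].mean()), "count": len(grp)}
        for a in cfg.actions:
            row[f"freq_{a}"] = float((grp["action"] == a).sum() / len(grp))
        rows.append(row)
    return ConditionalTable(
        data=pd.DataFrame(rows), treatment=treatment, successful_only=successful_only
    )


def weighted_regression(ct: ConditionalTable) -> RegressionFit:
    """WLS of bin mean contribution on x, weighted by bin observation counts.

    The slope sign is the reciprocity (positive) / compensation (negative)
    indicator; significance comes from the WLS t-statistic.
    """
    data = ct.data
    if data["x"].nunique() < 2:
        raise ValidationError(
            f"conditional table for {ct.treatment!r} has fewer than 2 distinct x bins; "
            "fit undefined"
        )
    x = sm.add_constant(data["x"].to_numpy(dtype=float))
    model = sm.WLS(data["mean"].to_numpy(dtype=float), x, weights=data["count"].to_numpy())
    res = model.fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        slope_pvalue=float(res.pvalues[1]),
        weights=data["count"].to_numpy(),
        n_bins=int(data["x"].nunique()),
    )


# ---------------------------------------------------------------------------
# Counts and per-player profile classification
# ---------------------------------------------------------------------------

def constant_contributor_count(
    table: ExperimentTable,
    treatment: str,
    action: int,
    successful_only: bool | None = None,
) -> int:
    """Number of players who chose ``action`` in every round of their game."""
    sub = table._filter_groups(treatment, successful_only)
    per_player = sub.groupby(["group_id", "player_id"])["action"]
    return int((per_player.agg(lambda s: (s == action).all())).sum())


def classify_profiles(
    table: ExperimentTable,
    treatment: str,
    method: str = "template",
    slope_cutoff: float = 0.05,
    match_cutoff: float = 0.8,
    successful_only: bool | None = None,
) -> pd.DataFrame:
    """Classify each player into a behavioral profile.

    ``method="template"`` (default) replays each of the five decision rules on
    the player's observed context (others' previous totals, previous
    cumulative totals, own remaining endowment) and assigns the best-matching
    rule; perfect-match ties prefer the unconditional rule (parsimony), and a
    best match below ``match_cutoff`` is labeled "other".

    ``method="slope"`` is the simpler sign-of-own-slope rule: a constant
    action gives the unconditional class; otherwise an OLS slope of the
    player's action on the others' previous total beyond ``slope_cutoff``
    (EMU/EMU) in magnitude gives reciprocal-like (positive) or
    compensator-like (negative), else "other".

    Only rounds before the target was reached are used — afterwards every
    rule plays 0 and observations carry no information.  Players with fewer
    than 2 informative rounds are labeled "other" and flagged.
    """
    if method not in ("template", "slope"):
        raise ValueError(f"unknown method {method!r}")
    cfg = table.config(treatment)
    sub = _with_context(table._filter_groups(treatment, successful_only))
    profiles = default_profiles(cfg)

    records = []
    for (gid, pid), hist in sub.groupby(["group_id", "player_id"]):
        hist = hist.sort_values("round")
        pre = hist[hist["cum_prev_total"] < cfg.threshold]
        flag = ""
        if len(pre) < 2:
            records.append(
                {"group_id": gid, "player_id": pid, "profile": "other", "flag": "too-short"}
            )
            continue
        actions = pre["action"].to_numpy()
        if method == "slope":
            label = _classify_slope(pre, actions, slope_cutoff)
        else:
            label = _classify_template(pre, cfg, profiles, match_cutoff)
        records.append({"group_id": gid, "player_id": pid, "profile": label, "flag": flag})
    return pd.DataFrame(records)


def _classify_slope(pre: pd.DataFrame, actions: np.ndarray, cutoff: float) -> str:
    if (actions == actions[0]).all():
        if actions[0] in (0, 2, 4):
            return f"unconditional-{actions[0]}"
        return "other"
    resp = pre[pre["round"] >= 2]
    if resp["others_prev_total"].nunique() < 2:
        return "other"
    x = sm.add_constant(resp["others_prev_total"].to_numpy(dtype=float))
    slope = float(sm.OLS(resp["action"].to_numpy(dtype=float), x).fit().params[1])
    if slope >= cutoff:
        return "reciprocal-like"
    if slope <= -cutoff:
        return "compensator-like"
    return "other"


_TEMPLATE_ORDER = (
    StrategyKind.ALWAYS0,
    StrategyKind.ALWAYS2,
    StrategyKind.ALWAYS4,
    StrategyKind.RECIPROCAL,
    StrategyKind.COMPENSATOR,
)

_TEMPLATE_LABEL = {
    StrategyKind.ALWAYS0: "unconditional-0",
    StrategyKind.ALWAYS2: "unconditional-2",
    StrategyKind.ALWAYS4: "unconditional-4",
    StrategyKind.RECIPROCAL: "reciprocal-like",
    StrategyKind.COMPENSATOR: "compensator-like",
}


def _classify_template(
    pre: pd.DataFrame,
    cfg: GameConfig,
    profiles: Mapping[StrategyKind, object],
    match_cutoff: float,
) -> str:
    own_cum = pre["action"].cumsum().shift(fill_value=0).to_numpy()
    remaining = cfg.endowment - own_cum
    rounds = pre["round"].to_numpy()
    others_prev = pre["others_prev_total"].to_numpy()
    cum_prev = pre["cum_prev_total"].to_numpy()
    observed = pre["action"].to_numpy()

    best_label, best_frac = "other", -1.0
    for kind in _TEMPLATE_ORDER:
        prof = profiles[kind]
        predicted = np.array(
            [
                decide(prof, int(t), float(x), float(c), int(r), cfg)
                for t, x, c, r in zip(rounds, others_prev, cum_prev, remaining)
            ]
        )
        frac = float((predicted == observed).mean())
        if frac > best_frac + 1e-12:  # strict improvement; earlier (unconditional) wins ties
            best_label, best_frac = _TEMPLATE_LABEL[kind], frac
    if best_frac < match_cutoff:
        return "other"
    return best_label
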