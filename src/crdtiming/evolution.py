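"""Stochastic evolutionary dynamics over the five strategies.

A well-mixed population of Z individuals, each committed to one of the five
strategies, revises choices by pairwise comparison: an individual copies a
randomly drawn model with probability ``1 / (1 + exp(-beta * (pi_model -
pi_self)))`` (the Fermi rule), where payoffs are the expected CRD payoffs of
groups of N sampled without replacement from the population (hypergeometric
weights).

In the small-mutation limit the population is monomorphic between rare
mutations, and the dynamics reduce to a Markov chain over the five pure
states whose transitions are pairwise fixation probabilities.  The chain's
stationary distribution weights the model outputs:

* ``eta`` — expected fraction of successful groups,
* ``reciprocal_prevalence`` — stationary mass of the reciprocal strategy
  among the strategies that contribute toward the target,
* ``polarization`` — fraction of players whose total contribution C deviates
  from the fair share F, in groups sampled from the stationary mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .config import ConfigError, GameConfig
from .game import (
    expected_outcome,
    static_round,
    play_group,
    termination_distribution,
)
from .strategies import (
    CONTRIBUTING_KINDS,
    STRATEGY_ORDER,
    StrategyKind,
    StrategyProfile,
    default_profiles,
)


@dataclass(frozen=True)
class PopulationConfig:
    """Finite-population parameters: size Z, selection strength beta (1/EMU),
    the game configuration and the five strategy profiles (canonical order)."""

    Z: int
    beta: float
    game: GameConfig
    profiles: tuple[StrategyProfile, ...]

    def __post_init__(self) -> None:
        if self.Z <= self.game.n_players:
            raise ConfigError(f"Z must exceed the group size, got Z={self.Z}")
        if self.beta < 0:
            raise ConfigError(f"beta must be >= 0, got {self.beta}")

    @classmethod
    def with_defaults(
        cls, game: GameConfig, Z: int = 50, beta: float = 0.004
    ) -> "PopulationConfig":
        profs = default_profiles(game)
        return cls(Z=Z, beta=beta, game=game, profiles=tuple(profs[k] for k in STRATEGY_ORDER))


@lru_cache(maxsize=4096)
def _mixed_group_payoffs(
    a: StrategyProfile, b: StrategyProfile, n_a: int, game: GameConfig
) -> tuple[float, float]:
    """Expected payoff of one A-player and one B-player in a group with
    ``n_a`` A's and ``N - n_a`` B's (nan for an absent type)."""
    n = game.n_players
    profiles = [a] * n_a + [b] * (n - n_a)
    out = expected_outcome(profiles, game)
    pay_a = float(out.expected_payoffs[0]) if n_a > 0 else float("nan")
    pay_b = float(out.expected_payoffs[-1]) if n_a < n else float("nan")
    return pay_a, pay_b


def pairwise_payoff(
    a: StrategyProfile, b: StrategyProfile, k: int, pop: PopulationConfig
) -> tuple[float, float]:
    """Expected payoffs of an A-player and a B-player when k individuals of
    the population of Z play A and Z-k play B.

    The N-1 co-players of a focal individual are drawn without replacement
    from the remaining Z-1, giving hypergeometric composition weights; each
    composition is scored by the exact game expectation.
    """
    z, n = pop.Z, pop.game.n_players
    if not 1 <= k <= z - 1:
        raise ValueError(f"k must be in [1, Z-1], got {k}")
    js = np.arange(n)  # number of A co-players
    w_a = hypergeom.pmf(js, z - 1, k - 1, n - 1)
    w_b = hypergeom.pmf(js, z - 1, k, n - 1)
    pay_a = sum(
        float(w) * _mixed_group_payoffs(a, b, j + 1, pop.game)[0]
        for j, w in zip(js, w_a)
        if w > 0
    )
    pay_b = sum(
        float(w) * _mixed_group_payoffs(a, b, j, pop.game)[1]
        for j, w in zip(js, w_b)
        if w > 0
    )
    return pay_a, pay_b


def payoff_vectors(
    a: StrategyProfile, b: StrategyProfile, pop: PopulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """pi_A(k), pi_B(k) for k = 1..Z-1 mutants, as arrays of length Z-1."""
    pairs = [pairwise_payoff(a, b, k, pop) for k in range(1, pop.Z)]
    arr = np.asarray(pairs)
    return arr[:, 0], arr[:, 1]


def fixation_probability(
    a: StrategyProfile, b: StrategyProfile, pop: PopulationConfig
) -> float:
    """Probability that a single A-mutant fixates in a population of B.

    Closed form for a birth-death chain under the Fermi rule,

        rho = 1 / (1 + sum_{i=1}^{Z-1} prod_{j=1}^{i} exp(-beta (pi_A(j) - pi_B(j)))),

    evaluated in log-space so large Z*beta*payoff products cannot overflow.
    Neutral drift (beta = 0 or equal payoffs) gives exactly 1/Z.
    """
    pi_a, pi_b = payoff_vectors(a, b, pop)
    log_terms = np.concatenate([[0.0], np.cumsum(-pop.beta * (pi_a - pi_b))])
    return float(np.exp(-logsumexp(log_terms)))


@dataclass
class EvoResult:
    """Small-mutation-limit results: pairwise fixation probabilities, the
    stationary distribution over monomorphic states, and the derived model
    metrics (filled by :func:`model_metrics`)."""

    strategy_names: tuple[str, ...]
    fixation: np.ndarray
    stationary: np.ndarray
    population: PopulationConfig
    eta: float | None = None
    reciprocal_prevalence: float | None = None
    polarization: float | None = None
    polarization_samples: int | None = None
    polarization_tol: float = 0.0
    seed: int | None = None

    def stationary_as_dict(self) -> dict[str, float]:
        return dict(zip(self.strategy_names, self.stationary))

    def summary(self) -> str:
        lines = [
            "Small-mutation-limit evolutionary dynamics",
            "=" * 46,
            f"Z = {self.population.Z}, beta = {self.population.beta}, "
            f"N = {self.population.game.n_players}",
            f"game: m0 = {self.population.game.m0}, w = {self.population.game.w:.4g}, "
            f"tau = {self.population.game.threshold}, r = {self.population.game.risk}",
            "",
            f"{'strategy':<14}{'stationary':>12}",
        ]
        for name, s in zip(self.strategy_names, self.stationary):
            lines.append(f"{name:<14}{s:>12.4f}")
        lines.append("")
        if self.eta is not None:
            lines.append(f"group achievement eta       : {self.eta:.4f}")
        if self.reciprocal_prevalence is not None:
            lines.append(f"reciprocal prevalence       : {self.reciprocal_prevalence:.4f}")
        if self.polarization is not None:
            lines.append(
                f"polarization (|C-F| > {self.polarization_tol:g})  : "
                f"{self.polarization:.4f}  [{self.polarization_samples} groups]"
            )
        return "\n".join(lines)


def transition_matrix(pop: PopulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Embedded chain over monomorphic states and the fixation matrix.

    ``T[s, s'] = rho(s' invades s) / (n_strat - 1)`` for s != s'; the
    fixation matrix entry ``[s, s']`` is that rho.
    """
    n = len(pop.profiles)
    fix = np.zeros((n, n))
    t = np.zeros((n, n))
    for i, resident in enumerate(pop.profiles):
        for j, mutant in enumerate(pop.profiles):
            if i == j:
                continue
            rho = fixation_probability(mutant, resident, pop)
            fix[i, j] = rho
            t[i, j] = rho / (n - 1)
        t[i, i] = 1.0 - t[i].sum()
    return t, fix


def stationary_distribution(pop: PopulationConfig) -> EvoResult:
    """Stationary distribution of the small-mutation-limit chain.

    Solves the left null space of ``T - I`` with the normalization row
    appended (least squares for robustness); entries are clipped at 0 and
    renormalized to absorb roundoff.
    """
    t, fix = transition_matrix(pop)
    n = t.shape[0]
    a = np.vstack([t.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    sol, residuals, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < n:
        raise np.linalg.LinAlgError(
            f"stationary solve is rank deficient (rank {rank} < {n}); "
            f"transition matrix:\n{t}"
        )
    sol = np.clip(sol, 0.0, None)
    sol /= sol.sum()
    names = tuple(p.kind.value for p in pop.profiles)
    return EvoResult(strategy_names=names, fixation=fix, stationary=sol, population=pop)


def _monomorphic_success(pop: PopulationConfig) -> np.ndarray:
    return np.array(
        [
            expected_outcome([p] * pop.game.n_players, pop.game).success_probability
            for p in pop.profiles
        ]
    )


def model_metrics(
    result: EvoResult,
    pop: PopulationConfig | None = None,
    n_samples: int = 10_000,
    tol: float = 0.0,
    seed: int | None = None,
    eta_estimator: str = "mixture",
) -> EvoResult:
    """Fill eta, reciprocal prevalence and polarization on a result.

    * eta: expected fraction of successful groups.  The default
      ``eta_estimator="mixture"`` scores the same stationary-mixture-sampled
      groups used for polarization (seeded Monte Carlo), so the two metrics
      describe one population state; ``"monomorphic"`` instead weights the
      closed-form success probability of monomorphic groups by the stationary
      distribution.
    * reciprocal prevalence: stationary mass of the reciprocal strategy over
      the strategies that contribute toward the target (undefined — nan —
      if the contributing mass is zero).
    * polarization: 1 - P(|C - F| <= tol) over ``n_samples`` groups whose
      members are drawn multinomially from the stationary mixture and whose
      length is drawn from the treatment's termination distribution (seeded).
      Traces are deterministic per (composition, length), so they are cached.
    """
    if eta_estimator not in ("mixture", "monomorphic"):
        raise ValueError(f"unknown eta_estimator {eta_estimator!r}")
    pop = pop or result.population
    game = pop.game
    stat = result.stationary

    contributing = np.array([p.kind in CONTRIBUTING_KINDS for p in pop.profiles])
    recip = np.array([p.kind is StrategyKind.RECIPROCAL for p in pop.profiles])
    denom = float(stat[contributing].sum())
    prevalence = float(stat[recip].sum() / denom) if denom > 0 else float("nan")

    rng = np.random.default_rng(seed)
    td = termination_distribution(game.m0, game.w)
    f = game.fair_share
    lengths = td.sample(rng, n_samples)
    comps = rng.multinomial(game.n_players, stat, size=n_samples)

    def _group(key: tuple[int, ...]) -> list[StrategyProfile]:
        return [p for p, c in zip(pop.profiles, key) for _ in range(c)]

    static_cache: dict[tuple[int, ...], int] = {}
    trace_cache: dict[tuple[tuple[int, ...], int], tuple[np.ndarray, bool]] = {}
    within = 0
    n_success = 0
    for comp, m in zip(comps, lengths):
        key = tuple(int(c) for c in comp)
        m_star = static_cache.get(key)
        if m_star is None:
            m_star = static_cache[key] = static_round(_group(key), game)
        m_eff = min(int(m), m_star)
        ckey = (key, m_eff)
        cached = trace_cache.get(ckey)
        if cached is None:
            trace = play_group(_group(key), game, m_eff)
            cached = trace_cache[ckey] = (
                trace.contributions_at(m_eff).astype(float),
                bool(trace.cum_totals[m_eff - 1] >= game.threshold),
            )
        contrib, success = cached
        within += int(np.count_nonzero(np.abs(contrib - f) <= tol))
        n_success += success

    polarization = 1.0 - within / (n_samples * game.n_players)
    if eta_estimator == "monomorphic":
        eta = float(np.dot(stat, _monomorphic_success(pop)))
    else:
        eta = n_success / n_samples

    return replace(
        result,
        eta=eta,
        reciprocal_prevalence=prevalence,
        polarization=polarization,
        polarization_samples=n_samples,
        polarization_tol=tol,
        seed=seed,
    )


class EvolutionaryModel:
    """Model object for the small-mutation-limit dynamics.

    Parameters follow the study's defaults (Z = 50, beta = 0.004, the five
    default strategy profiles).  ``fit()`` solves the chain and computes the
    derived metrics, returning an :class:`EvoResult`.

    Examples
    --------
    >>> from crdtiming.config import PRESETS
    >>> model = EvolutionaryModel(PRESETS["HU"])
    >>> res = model.fit(seed=0)
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        game: GameConfig,
        Z: int = 50,
        beta: float = 0.004,
        profiles: Sequence[StrategyProfile] | None = None,
    ) -> None:
        if profiles is None:
            pop = PopulationConfig.with_defaults(game, Z=Z, beta=beta)
        else:
            pop = PopulationConfig(Z=Z, beta=beta, game=game, profiles=tuple(profiles))
        self.population = pop

    def fit(
        self,
        n_polarization_samples: int = 10_000,
        tol: float = 0.0,
        seed: int | None = None,
        eta_estimator: str = "mixture",
    ) -> EvoResult:
        result = stationary_distribution(self.population)
        return model_metrics(
            result,
            self.population,
            n_samples=n_polarization_samples,
            tol=tol,
            seed=seed,
            eta_estimator=eta_estimator,
        )
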