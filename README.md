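# crdtiming

Tools for studying **timing uncertainty in collective risk dilemmas (CRDs)**:
an exact game engine for the multi-round threshold public goods game with a
geometrically distributed ending round, a five-strategy stochastic
evolutionary model in finite populations, the analysis stages used on
behavioral decision data from such experiments, and a seeded synthetic-data
generator with planted ground truth.

It is aimed at researchers in behavioral game theory and evolutionary
dynamics who want a tested, reproducible reference implementation of this
game class and its standard analyses.

## The game

A group of `N = 6` players each holds an endowment `E = 40` EMU and, each
round, contributes 0, 2 or 4 EMU to a common pool. If the pool reaches the
target `τ = 120` EMU before the game ends, everyone keeps what remains of
their endowment; otherwise each player loses the remainder with probability
`r = 0.9`. The *fair share* is `F = E/2 = 20` EMU: if everyone contributes
exactly F the target is met and gains are equal.

Timing uncertainty enters through the ending round. Rounds `1..m0` are
always played; after round `m0` (and after every later round) the game stops
with probability `w`, so the ending round is `m0 + Geometric₀(w)` with mean
`m0 + (1−w)/w`. Three presets share a mean length of 10 rounds:

| preset | m0 | w   | interpretation          |
|--------|----|-----|-------------------------|
| NU     | 10 | 1   | no timing uncertainty   |
| LU     | 8  | 1/3 | low timing uncertainty  |
| HU     | 6  | 1/5 | high timing uncertainty |

## The evolutionary model

Five deterministic one-round-memory strategies — *always-0*, *always-2*,
*always-4*, *compensator* (gives 4 when the others did not contribute) and
*reciprocal* (gives 4 as long as the others contribute) — compete in a
well-mixed population of `Z = 50` individuals. Groups of N are sampled
hypergeometrically, payoffs are exact expectations over the ending-round
distribution, and individuals imitate via the Fermi rule
`p = 1/(1 + e^{−β Δπ})` with selection strength `β = 0.004`. In the
small-mutation limit the dynamics reduce to a Markov chain over the five
monomorphic states whose transitions are closed-form pairwise fixation
probabilities; its stationary distribution yields the model metrics: group
achievement η, the prevalence of the reciprocal strategy among contributing
strategies, and a polarization index `1 − P(|C − F| ≤ tol)` over groups
sampled from the stationary mixture.

## Worked example

```python
from crdtiming import PRESETS, EvolutionaryModel

res = EvolutionaryModel(PRESETS["HU"]).fit(seed=42)
print(res.summary())
```

```
Small-mutation-limit evolutionary dynamics
==============================================
Z = 50, beta = 0.004, N = 6
game: m0 = 6, w = 0.2, tau = 120, r = 0.9

strategy        stationary
always-0            0.4020
always-2            0.2379
always-4            0.0489
compensator         0.2278
reciprocal          0.0834

group achievement eta       : 0.1633
reciprocal prevalence       : 0.1394
polarization (|C-F| > 0)  : 0.9273  [10000 groups]
```

The stationary column is the long-run fraction of time the population spends
in each monomorphic state; 13.9% of the contributing mass sits on the
reciprocal strategy (against 8.6% in NU), and 92.7% of players in sampled
groups end away from the fair share — both larger than without timing
uncertainty, while η moves comparatively little across treatments.

The analysis pipeline recovers planted behavior from data. A synthetic
high-uncertainty cohort of 40 groups, half reciprocal players:

```python
from crdtiming import (CohortSpec, StrategyKind, conditional_table,
                       generate, weighted_regression)

spec = CohortSpec("HU", 40, {StrategyKind.RECIPROCAL: 0.5,
                             StrategyKind.ALWAYS2: 0.3,
                             StrategyKind.ALWAYS0: 0.2}, seed=7)
table, truth = generate(spec)
fit = weighted_regression(conditional_table(table, "HU", pre_success_only=True))
print(f"slope = {fit.slope:.3f} +/- {fit.slope_se:.3f} (p = {fit.slope_pvalue:.2e})")
```

```
slope = 0.142 +/- 0.048 (p = 1.58e-02)
```

The positive slope of focal contributions on the others' previous-round
total is the signature of group reciprocity; a compensator-heavy cohort
gives a negative slope.

The same stages run from the shell:

```sh
crdtiming generate --treatment HU --n-groups 40 \
    --mixture "reciprocal=0.5,always-2=0.3,always-0=0.2" --seed 7 \
    --out cohort.csv --ground-truth truth.json
crdtiming analyze --input cohort.csv --treatment HU --outdir results/
crdtiming evolve --treatments NU,LU,HU --seed 7 --out model.csv
```

Each run writes a JSON manifest sufficient to replay it exactly. Decision
tables from the archived experimental deposit (Dryad
doi:10.5061/dryad.5qfttdz2t) can be ingested through
`load_table(path, schema_map=...)`; see `DRYAD_SCHEMA_TEMPLATE`.

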