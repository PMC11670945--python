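# ipdlab

Tournament simulation and winner-feature analysis for the Iterated
Prisoner's Dilemma (IPD).

Researchers in evolutionary game theory evaluate IPD strategies by playing
them against each other in round-robin computer tournaments.  `ipdlab` is a
self-contained pipeline for doing this reproducibly: a match engine with
action noise and geometrically distributed match lengths, a catalog of
canonical strategies (Tit For Tat and its variants, Pavlov, Grudger,
Gradual, zero-determinant strategies, meta ensembles, plus generic
memory-one / finite-state / lookup-table families), four tournament types
(standard, noisy, probabilistic ending, noisy probabilistic ending), a
randomized trial sampler, and a statistical layer that asks *which
behavioral features predict tournament success*.

## The quantities at the core

* **Stage game** — payoffs R, S, T, P with T > R > P > S and 2R > T + S
  (defaults 3, 0, 5, 1).
* **Normalized rank** — r = R/(N − 1) for a strategy ranked R out of N
  (0 = winner, 1 = last); performance across tournaments is summarized by
  the median r̄.
* **Cooperation statistics** — the cooperation rating C_r, the four
  conditional cooperation rates (CC→C, CD→C, DC→C, DD→C), and C_r relative
  to the tournament aggregates C_max, C_min, C_mean, C_median.
* **SSE to zero-determinant behavior** — the residual of the nonnegative
  least-squares projection of a strategy's observed memory-one cooperation
  vector onto the extortionate zero-determinant family
  p̃ = φ[(S_x − P·1) − χ(S_y − P·1)]; SSE = 0 means exactly ZD-like.
* **Analysis** — per tournament type, Spearman correlations of each feature
  with r and the median score, a multivariate OLS regression of r on a
  collinearity-pruned feature list, and the feature distributions of
  tournament winners.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from ipdlab import play_match, sse_to_zd, zd_vector
from ipdlab.game import MatchConfig
from ipdlab.strategies import catalog
from ipdlab.tournament import TournamentConfig, run_tournament

registry = catalog()

# A 5-round match: Tit For Tat against an unconditional defector.
tft, dfc = play_match(
    registry["Tit For Tat"].factory(),
    registry["Defector"].factory(),
    MatchConfig(turns=5, seed=0),
)
print([a.name for a in tft.focal_actions()], tft.total_focal, dfc.total_focal)
# ['C', 'D', 'D', 'D', 'D'] 4.0 9.0
#   TFT is exploited once (S = 0), then mutual defection: 4/5 = 0.8 per
#   turn against the defector's (5 + 4)/5 = 1.8.

# A 3-player tournament, 10 turns, one repetition.
summary = run_tournament(TournamentConfig(
    players=[registry[n] for n in ("Cooperator", "Defector", "Tit For Tat")],
    turns=10, repetitions=1, seed=0,
))
print(summary.to_frame()[["rank", "name", "median_score", "wins"]])
#    rank         name  median_score  wins
# 0     0     Defector          3.20     2
# 1     1  Tit For Tat          1.95     0
# 2     2   Cooperator          1.50     0
#   In this tiny pool the defector wins: 5.0/turn off the cooperator and
#   1.4/turn off TFT average to 3.2.

# Zero-determinant detection: an exact extortioner fits with zero residual.
fit = sse_to_zd(zd_vector(phi=0.1, chi=2.0))
print(round(fit.sse, 12), round(fit.phi, 6), round(fit.chi, 6))
# 0.0 0.1 2.0
```

## Analysis pipeline

The numbered drivers under `analysis/` run the full pipeline at desk scale
and write their tables under `results/`:

```bash
python analysis/01_run_campaign.py       # 40 randomized trials x 4 tournament types
python analysis/02_analyze_features.py   # correlations, rank regression, winner profiles
python analysis/03_synthetic_recovery.py # planted-coefficient recovery validation
```

The same stages are available as a CLI: `ipdlab run-trials`,
`ipdlab summarize`, `ipdlab analyze`, `ipdlab simulate-features`
(see `--help`).

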