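"""Randomized trial sampler and campaign orchestration.

A *trial* draws a tournament configuration at random — the number of players
N, the player set, the repetition count k, the match length n, the noise
level p_n and the ending probability p_e — and then runs the four tournament
types (standard, noisy, probabilistic ending, noisy probabilistic ending) on
the same player set with the same k.  The shipped default ranges are the
study ranges (N in [3, 195] clipped to the catalog size, k in [10, 100],
n in [1, 200], p_n in [0, 1], p_e in (0, 1]); a desk-scale profile with
smaller tournaments is provided for quick runs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, build_feature_table
from .game import DEFAULT_PAYOFFS, PayoffMatrix
from .strategies import StrategySpec, catalog as default_catalog
from .tournament import ResultSummary, TournamentConfig, run_tournament

__all__ = [
    "TrialRanges",
    "PAPER_RANGES",
    "DESK_RANGES",
    "TrialConfig",
    "TrialRecord",
    "TOURNAMENT_TYPES",
    "sample_trial",
    "run_trial",
    "run_campaign",
    "TRIAL_COLUMNS",
]

TOURNAMENT_TYPES = (
    "standard",
    "noisy",
    "probabilistic_ending",
    "noisy_probabilistic_ending",
)

TRIAL_COLUMNS = ["trial", "seed", "N", "k", "n", "p_n", "p_e", "players"]


@dataclass(frozen=True)
class TrialRanges:
    """Inclusive sampling ranges for the trial sampler.

    ``ending`` is sampled from the half-open interval (low, high]: an ending
    probability of exactly 0 would never terminate a match.
    """

    n_players: Tuple[int, int] = (3, 195)
    repetitions: Tuple[int, int] = (10, 100)
    turns: Tuple[int, int] = (1, 200)
    noise: Tuple[float, float] = (0.0, 1.0)
    ending: Tuple[float, float] = (0.0, 1.0)
    length_cap: int = 10_000


PAPER_RANGES = TrialRanges()

# Desk-scale profile: small tournaments that complete in seconds, same
# distributional shape for the probability parameters.
DESK_RANGES = TrialRanges(
    n_players=(3, 12), repetitions=(4, 10), turns=(1, 60), length_cap=500
)


@dataclass(frozen=True)
class TrialConfig:
    """One sampled trial: the shared parameters of its four tournaments."""

    seed: int
    players: Tuple[str, ...]
    repetitions: int
    turns: int
    noise: float
    ending: float
    length_cap: int = 10_000
    trial: Optional[int] = None

    @property
    def n_players(self) -> int:
        return len(self.players)


@dataclass
class TrialRecord:
    config: TrialConfig
    summaries: Dict[str, ResultSummary]


def sample_trial(
    seed: int,
    registry: Optional[Mapping[str, StrategySpec]] = None,
    ranges: TrialRanges = PAPER_RANGES,
    trial: Optional[int] = None,
) -> TrialConfig:
    """Draw one trial configuration; fully determined by ``seed``.

    N is drawn uniformly from the configured range (clipped to the catalog
    size), then N distinct strategies uniformly without replacement, then
    k, n, p_n and p_e from their ranges.
    """
    registry = registry if registry is not None else default_catalog()
    names = sorted(registry)
    if not names:
        raise ValueError("empty strategy catalog")
    lo, hi = ranges.n_players
    hi = min(hi, len(names))
    if lo > hi:
        raise ValueError(
            f"catalog of {len(names)} strategies cannot fill N >= {lo} players"
        )
    rng = np.random.default_rng(seed)
    n_players = int(rng.integers(lo, hi + 1))
    players = tuple(rng.choice(names, size=n_players, replace=False))
    repetitions = int(rng.integers(ranges.repetitions[0], ranges.repetitions[1] + 1))
    turns = int(rng.integers(ranges.turns[0], ranges.turns[1] + 1))
    noise = float(rng.uniform(ranges.noise[0], ranges.noise[1]))
    e_lo, e_hi = ranges.ending
    ending = float(e_hi - rng.uniform(0.0, e_hi - e_lo))  # in (e_lo, e_hi]
    return TrialConfig(
        seed=int(seed),
        players=players,
        repetitions=repetitions,
        turns=turns,
        noise=noise,
        ending=ending,
        length_cap=ranges.length_cap,
        trial=trial,
    )


def _tournament_seed(trial_seed: int, type_index: int) -> int:
    ss = np.random.SeedSequence(trial_seed, spawn_key=(type_index,))
    return int(ss.generate_state(1, np.uint32)[0])


def run_trial(
    config: TrialConfig,
    registry: Optional[Mapping[str, StrategySpec]] = None,
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
) -> TrialRecord:
    """Run the four tournaments of one trial on the same player set."""
    registry = registry if registry is not None else default_catalog()
    players = [registry[name] for name in config.players]
    settings = {
        "standard": dict(turns=config.turns, noise=0.0),
        "noisy": dict(turns=config.turns, noise=config.noise),
        "probabilistic_ending": dict(ending=config.ending, noise=0.0),
        "noisy_probabilistic_ending": dict(ending=config.ending, noise=config.noise),
    }
    summaries = {}
    for idx, ttype in enumerate(TOURNAMENT_TYPES):
        tc = TournamentConfig(
            players=players,
            repetitions=config.repetitions,
            seed=_tournament_seed(config.seed, idx),
            length_cap=config.length_cap,
            **settings[ttype],
        )
        summaries[ttype] = run_tournament(tc, payoffs)
    return TrialRecord(config=config, summaries=summaries)


def _trial_row(config: TrialConfig) -> dict:
    return {
        "trial": config.trial,
        "seed": config.seed,
        "N": config.n_players,
        "k": config.repetitions,
        "n": config.turns,
        "p_n": config.noise,
        "p_e": config.ending,
        "players": ";".join(config.players),
    }


def run_campaign(
    n_trials: int,
    master_seed: int,
    out_dir,
    ranges: TrialRanges = PAPER_RANGES,
    registry: Optional[Mapping[str, StrategySpec]] = None,
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
    write_summaries: bool = True,
    resume: bool = True,
    progress: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``n_trials`` independent trials, streaming results to ``out_dir``.

    Writes ``trials.csv`` (one row per trial), ``features.csv`` (one row per
    tournament-type x strategy), per-tournament summary CSVs under
    ``summaries/`` and a ``manifest.json`` logging the seed, ranges and
    completed trial indices.  Per-trial seeds derive deterministically from
    ``master_seed``, so a campaign is resumable by trial index and identical
    whether run serially or restarted.
    """
    registry = registry if registry is not None else default_catalog()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries_dir = out / "summaries"
    if write_summaries:
        summaries_dir.mkdir(exist_ok=True)
    manifest_path = out / "manifest.json"
    trials_path = out / "trials.csv"
    features_path = out / "features.csv"

    # JSON round trip normalizes tuples to lists so manifests compare equal.
    params = json.loads(
        json.dumps(
            {
                "master_seed": int(master_seed),
                "n_trials": int(n_trials),
                "ranges": dataclasses.asdict(ranges),
            }
        )
    )
    completed: List[int] = []
    if resume and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if {k: manifest[k] for k in params} != params:
            raise ValueError(
                f"existing campaign at {out} was run with different parameters"
            )
        completed = list(manifest.get("completed", []))
    else:
        _write_headers(trials_path, TRIAL_COLUMNS)
        _write_headers(features_path, FEATURE_COLUMNS)

    trial_seeds = np.random.default_rng(master_seed).integers(
        0, 2**31 - 1, size=n_trials
    )
    classifiers = {name: spec.classifiers() for name, spec in registry.items()}

    for index in range(n_trials):
        if index in completed:
            continue
        config = sample_trial(
            int(trial_seeds[index]), registry, ranges, trial=index
        )
        record = run_trial(config, registry, payoffs)
        pd.DataFrame([_trial_row(config)], columns=TRIAL_COLUMNS).to_csv(
            trials_path, mode="a", header=False, index=False
        )
        features = build_feature_table([record], classifiers, payoffs)
        features.to_csv(features_path, mode="a", header=False, index=False)
        if write_summaries:
            for ttype, summary in record.summaries.items():
                summary.write_csv(summaries_dir / f"trial_{index:05d}_{ttype}.csv")
        completed.append(index)
        manifest_path.write_text(
            json.dumps({**params, "completed": completed}, indent=1)
        )
        if progress:
            print(f"trial {index + 1}/{n_trials} done (N={config.n_players}, "
                  f"k={config.repetitions}, n={config.turns})")

    trials_df = pd.read_csv(trials_path)
    features_df = pd.read_csv(features_path)
    return trials_df, features_df


def _write_headers(path: Path, columns: Sequence[str]) -> None:
    pd.DataFrame(columns=list(columns)).to_csv(path, index=False)
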