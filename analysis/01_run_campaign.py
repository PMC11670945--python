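"""Run a desk-scale randomized tournament campaign.

Samples trials with the Algorithm-style sampler (four tournament types per
trial on a shared player set) at the desk profile (N in [3, 12], k in
[4, 10], n in [1, 60], p_n uniform on [0, 1], p_e uniform on (0, 1], match
cap 500) over the full canonical strategy catalog, and streams trials.csv /
features.csv / per-tournament summaries to results/campaign/.
"""

from pathlib import Path

from ipdlab.experiment import DESK_RANGES, run_campaign

N_TRIALS = 40
MASTER_SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "campaign"


def main() -> None:
    trials, features = run_campaign(
        n_trials=N_TRIALS,
        master_seed=MASTER_SEED,
        out_dir=OUT,
        ranges=DESK_RANGES,
        progress=True,
    )
    low_noise = (trials["p_n"] <= 0.1).sum()
    low_ending = (trials["p_e"] <= 0.1).sum()
    print(f"\ncampaign complete: {len(trials)} trials, {len(features)} feature rows")
    print(f"low-noise trials (p_n <= 0.1): {low_noise}; "
          f"short-ending trials (p_e <= 0.1): {low_ending}")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
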