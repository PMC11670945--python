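"""Analyze the campaign's feature table.

Reads results/campaign/features.csv and writes, per tournament type, the
Spearman correlations of every feature with the normalized rank and the
median score, the multivariate OLS rank regression, and the winners'
feature-distribution summaries, to results/analysis/.
"""

from pathlib import Path

import pandas as pd

from ipdlab.analysis import fit_rank_regression, write_analysis

ROOT = Path(__file__).resolve().parents[1]
FEATURES = ROOT / "results" / "campaign" / "features.csv"
OUT = ROOT / "results" / "analysis"


def main() -> None:
    table = pd.read_csv(FEATURES)
    paths = write_analysis(table, OUT)
    for name, path in paths.items():
        print(f"wrote {name}: {path}")

    results = fit_rank_regression(table)
    print("\nrank-regression fit quality (adjusted R^2):")
    for ttype, res in results.items():
        print(f"  {ttype:28s} {res.rsquared_adj:6.3f}  (n={res.nobs})")
    corr = pd.read_csv(paths["correlations"])
    sse = corr[(corr["feature"] == "SSE") & (corr["target"] == "normalized_rank")]
    print("\nSpearman(SSE, normalized rank) per type:")
    for _, row in sse.iterrows():
        print(f"  {row['tournament_type']:28s} {row['spearman']:+.3f}")


if __name__ == "__main__":
    main()
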