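"""Summarize the simulated study into the figure-style tables.

Per-condition success counts, contributions by role/round/rank difference,
contributions split by outcome, offers and thresholds against the 4k
equilibrium line, and the rank-earnings correlation.  Tables land in
results/figures/.  Run 01_simulate_study.py first.
"""

from pathlib import Path

import pandas as pd

from hiercoop import analysis as an
from hiercoop.game_core import read_records_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    files = sorted((ROOT / "data").glob("*.csv"))
    if not files:
        raise SystemExit("no data found: run analysis/01_simulate_study.py first")
    df = pd.concat([read_records_csv(f) for f in files], ignore_index=True)

    out = ROOT / "figures"
    out.mkdir(parents=True, exist_ok=True)
    tables = an.summarize_figures(df)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.csv", index=False)

    print("mean per-player successes (of 9) by condition:")
    print(tables["fig1a"].round(2).to_string(index=False))
    print("\noffers and thresholds vs k (hierarchy, full experiment):")
    fig4 = tables["fig4"]
    print(fig4[fig4["treatment"].isin(["earned", "random"])]
          .round(2).to_string(index=False))

    rho = an.rank_earnings_correlation(df)
    print(f"\nrank-earnings Spearman correlation (higher status = larger): {rho:.3f}")
    print(f"-> {len(tables)} tables written to {out}")


if __name__ == "__main__":
    main()
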