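#!/usr/bin/env python
"""Build the study-style circular-statistics table from simulated crossings.

Reads results/simulation/crossings.csv and reports, per condition x
height: n, mean direction, 95% CI, Rayleigh Z and p, V toward the nest
(0 deg) and its p, and whether the nest direction falls inside the CI.
Every statistic is recomputable from the crossings CSV alone.
"""

from pathlib import Path

import pandas as pd

from trunknav import circular_stats as cs

IN = Path("results/simulation/crossings.csv")
OUT = Path("results/stats")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(IN)
    table = cs.summary_table(df)
    table.to_csv(OUT / "stats_table.csv", index=False)
    pd.set_option("display.width", 160)
    print(table.to_string(index=False))
    print(f"table -> {OUT / 'stats_table.csv'}")


if __name__ == "__main__":
    main()
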