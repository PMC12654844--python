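#!/usr/bin/env python
"""Group statistics on the simulated screen's phenotypes.

Kruskal-Wallis + Dunn (BH-adjusted) compares Amax across cycloheximide
doses with a compact-letter display; a two-factor ANOVA (type II) partitions
the variance of normalized lag into dose, strain, their interaction and
residual.  Censored lags are excluded (counted on stdout).  Output:
results/report/ (report.json, comparisons.csv, partition.csv, figures).
"""

from pathlib import Path

import pandas as pd

from spotlag.stats_report import anova_partition, kruskal_dunn, report

root = Path(__file__).resolve().parents[1]
results = root / "results"

df = pd.read_csv(results / "phenotypes.csv")
norm = pd.to_numeric(
    df["normalized_lag_days"].astype(str).str.replace(">", "", regex=False),
    errors="coerce",
)
censored = df["normalized_lag_days"].astype(str).str.startswith(">")
df["_norm"] = norm.where(~censored)
usable = df.dropna(subset=["_norm"])
print(f"{censored.sum()} censored normalized lags excluded from both tests")

gc = kruskal_dunn(
    {f"{d:g}": g["amax_px"].to_numpy() for d, g in df.groupby("dose")}
)
print(f"Amax vs dose: Kruskal-Wallis H = {gc.h_statistic:.1f} "
      f"(p = {gc.p_value:.2e}); letters: {gc.letters}")

# the interaction term needs every dose x strain cell occupied: censoring
# empties cells for the least tolerant strains, so keep complete cases only
n_doses = usable["dose"].nunique()
complete = usable.groupby("strain")["dose"].transform("nunique") == n_doses
dropped = usable.loc[~complete, "strain"].nunique()
if dropped:
    print(f"{dropped} strain(s) without observations at every dose excluded "
          f"from the variance partition")
vp = anova_partition(
    usable[complete].rename(columns={"_norm": "normalized_lag"}),
    "normalized_lag",
    ["dose", "strain"],
    interactions=[("dose", "strain")],
)
for _, row in vp.table.iterrows():
    print(f"  {row['term']:<12} {row['fraction_pct']:5.1f}% of SS")

summary = report(df, [gc], [vp], results / "report")
print(f"report -> {results/'report'} ({len(summary['figures'])} figures)")
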