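"""Group statistics: Kruskal-Wallis with Dunn post hoc and compact letters,
and the factorial-ANOVA variance partition of normalized lag.

Censored lags are excluded from both tests by default (their count is
logged); rank tests on mixed censored data would need survival machinery
that is out of scope here.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    factor: str
    levels: list[str]
    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: level_a, level_b, z, p_raw, p_adj
    letters: dict[str, str]
    alpha: float = 0.05


@dataclass
class VariancePartition:
    terms: list[str]
    table: pd.DataFrame  # columns: term, sum_sq, df, fraction_pct

    def fraction(self, term: str) -> float:
        row = self.table.loc[self.table["term"] == term, "fraction_pct"]
        if row.empty:
            raise KeyError(f"unknown term {term!r}")
        return float(row.iloc[0])


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z statistics on the pooled midranks, with tie correction."""
    levels = list(groups)
    pooled = np.concatenate([groups[g] for g in levels])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    rank_by_level: dict[str, np.ndarray] = {}
    start = 0
    for g in levels:
        n = len(groups[g])
        rank_by_level[g] = ranks[start : start + n]
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(levels, 2):
        na, nb = len(groups[a]), len(groups[b])
        num = rank_by_level[a].mean() - rank_by_level[b].mean()
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb)
        z = num / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"level_a": a, "level_b": b, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def compact_letter_display(
    levels: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letters for a pairwise significance relation.

    Levels sharing a letter are not significantly different; levels that
    differ share no letter.
    """
    sig = {frozenset(p) for p in significant_pairs}
    # letter groups are maximal sets of mutually non-different levels
    groups: list[set[str]] = [set(levels)] if levels else []
    for a, b in (tuple(s) for s in sig):
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {a}, g - {b}])
            else:
                new_groups.append(g)
        # absorb: drop groups contained in another
        groups = [
            g
            for g in new_groups
            if g and not any(g < h for h in new_groups if h is not g)
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    ordered = sorted(groups, key=lambda g: min(levels.index(x) for x in g))
    letters = {lv: "" for lv in levels}
    for i, g in enumerate(ordered):
        ch = alphabet[i % len(alphabet)]
        for lv in levels:
            if lv in g:
                letters[lv] += ch
    return letters


def kruskal_dunn(
    values_by_group: dict[str, "np.ndarray | list"],
    alpha: float = 0.05,
    p_adjust: str = "fdr_bh",
) -> GroupComparison:
    """Kruskal-Wallis H test with Dunn pairwise post hoc and compact letters.

    ``p_adjust`` is any method statsmodels' ``multipletests`` knows
    (``fdr_bh`` default, ``holm``, or ``none`` for unadjusted p values).
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    levels = list(groups)
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        # identical constant everywhere: no evidence of any difference
        h, p = 0.0, 1.0
        pairs = pd.DataFrame(
            [
                {"level_a": a, "level_b": b, "z": 0.0, "p_raw": 1.0, "p_adj": 1.0}
                for a, b in itertools.combinations(levels, 2)
            ]
        )
        letters = {lv: "a" for lv in levels}
        return GroupComparison(
            "group", levels, h, p, pairs, letters, alpha
        )
    h, p = sps.kruskal(*groups.values())
    pairs = _dunn_pairwise(groups)
    if p_adjust in (None, "none"):
        pairs["p_adj"] = pairs["p_raw"]
    else:
        pairs["p_adj"] = multipletests(pairs["p_raw"], method=p_adjust)[1]
    sig = {
        (r.level_a, r.level_b)
        for r in pairs.itertuples()
        if r.p_adj < alpha
    }
    letters = compact_letter_display(levels, sig)
    return GroupComparison("group", levels, float(h), float(p), pairs, letters, alpha)


def kruskal_h_brute(values_by_group: dict) -> float:
    """Textbook rank-sum formula for H (no tie correction); small-data oracle."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def anova_partition(
    records: pd.DataFrame,
    response: str,
    factors: list[str],
    interactions: list[tuple[str, str]] | None = None,
    ss_type: int = 2,
) -> VariancePartition:
    """Factorial ANOVA variance partition of ``response``.

    Fits an OLS on categorical encodings of ``factors`` plus the requested
    pairwise ``interactions``, computes per-term sums of squares of the
    configured type (II by default: order-invariant and appropriate once
    censored records unbalance the design), and expresses each term --
    residual included -- as a percentage of the summed SS, so fractions
    always total 100.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.copy()
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor {f!r} missing from records")
        df[f] = df[f].astype(str)
    terms = [f"C({f})" for f in factors]
    for a, b in interactions or []:
        terms.append(f"C({a}):C({b})")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    if model.df_resid > 0 and np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design for terms {terms}: some effects are aliased"
        )
    anova = sm.stats.anova_lm(model, typ=ss_type)
    anova = anova.rename(index=lambda s: s.strip())
    rows = []
    total_ss = float(anova["sum_sq"].sum())
    for term, row in anova.iterrows():
        name = (
            term.replace("C(", "").replace(")", "").replace(":", "x")
            if term != "Residual"
            else "residual"
        )
        rows.append(
            {
                "term": name,
                "sum_sq": float(row["sum_sq"]),
                "df": float(row["df"]),
                "fraction_pct": 100.0 * float(row["sum_sq"]) / total_ss,
            }
        )
    table = pd.DataFrame(rows)
    return VariancePartition(terms=list(table["term"]), table=table)


def report(
    phenotypes: pd.DataFrame,
    comparisons: list[GroupComparison],
    partitions: list[VariancePartition],
    out_dir,
) -> dict:
    """Write the machine-readable summary and the standard figures.

    Produces ``report.json``, ``comparisons.csv``, ``partition.csv`` and
    PNG figures (Amax distributions by dose, normalized-lag boxplots by
    group x dose, lag-class bubble chart) under ``out_dir``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_records": int(len(phenotypes)), "figures": []}

    if comparisons:
        pd.concat(
            [
                c.pairwise.assign(
                    factor=c.factor,
                    h_statistic=c.h_statistic,
                    p_value=c.p_value,
                )
                for c in comparisons
            ]
        ).to_csv(out / "comparisons.csv", index=False)
        summary["comparisons"] = [
            {
                "factor": c.factor,
                "H": c.h_statistic,
                "p": c.p_value,
                "letters": c.letters,
            }
            for c in comparisons
        ]
    if partitions:
        pd.concat([p.table for p in partitions]).to_csv(
            out / "partition.csv", index=False
        )
        summary["partitions"] = [
            {r["term"]: r["fraction_pct"] for _, r in p.table.iterrows()}
            for p in partitions
        ]

    def _savefig(fig, name):
        fig.savefig(out / name, dpi=110)
        plt.close(fig)
        summary["figures"].append(name)

    if "amax_px" in phenotypes.columns and "dose" in phenotypes.columns:
        fig, ax = plt.subplots(figsize=(7, 4))
        doses = sorted(phenotypes["dose"].unique())
        data = [
            phenotypes.loc[phenotypes["dose"] == d, "amax_px"].to_numpy()
            for d in doses
        ]
        ax.boxplot(data, tick_labels=[f"{d:g}" for d in doses])
        if comparisons:
            letters = comparisons[0].letters
            for i, d in enumerate(doses, start=1):
                if f"{d:g}" in letters:
                    ax.annotate(
                        letters[f"{d:g}"],
                        (i, ax.get_ylim()[1]),
                        ha="center",
                        va="bottom",
                    )
        ax.set_xlabel("cycloheximide dose (g/L)")
        ax.set_ylabel("Amax (px)")
        _savefig(fig, "amax_by_dose.png")

    df = phenotypes.copy()
    if "normalized_lag_days" in df.columns:
        norm = pd.to_numeric(
            df["normalized_lag_days"].astype(str).str.replace(">", "", regex=False),
            errors="coerce",
        )
        cen = df["normalized_lag_days"].astype(str).str.startswith(">")
        df["_norm_lag"] = norm.where(~cen)
        sub = df.dropna(subset=["_norm_lag"])
        if not sub.empty and {"genetic_group", "dose"} <= set(sub.columns):
            fig, ax = plt.subplots(figsize=(8, 4))
            keys = sorted(
                sub.groupby(["genetic_group", "dose"], observed=True).groups
            )
            ax.boxplot(
                [
                    sub[
                        (sub["genetic_group"] == g) & (sub["dose"] == d)
                    ]["_norm_lag"].to_numpy()
                    for g, d in keys
                ],
                tick_labels=[f"{g}\n{d:g}" for g, d in keys],
            )
            ax.set_ylabel("normalized lag (days)")
            fig.autofmt_xdate(rotation=60)
            _savefig(fig, "normalized_lag_by_group_dose.png")

        if {"lag_days", "genetic_group", "dose"} <= set(df.columns):
            lag = pd.to_numeric(
                df["lag_days"].astype(str).str.replace(">", "", regex=False),
                errors="coerce",
            )
            ok = ~df["lag_days"].astype(str).str.startswith(">")
            bub = df.assign(_lag=lag.where(ok)).dropna(subset=["_lag"])
            if not bub.empty:
                fig, ax = plt.subplots(figsize=(8, 4))
                cnt = (
                    bub.groupby(["genetic_group", "_lag"], observed=True)
                    .size()
                    .reset_index(name="n")
                )
                ygroups = sorted(cnt["genetic_group"].unique())
                ax.scatter(
                    cnt["_lag"],
                    [ygroups.index(g) for g in cnt["genetic_group"]],
                    s=cnt["n"] * 20,
                    alpha=0.6,
                )
                ax.set_yticks(range(len(ygroups)), ygroups)
                ax.set_xlabel("lag class (days)")
                _savefig(fig, "lag_class_bubble.png")

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return summary
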