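import itertools

import numpy as np
import pandas as pd
import pytest

from spotlag.stats_report import (
    anova_partition,
    compact_letter_display,
    kruskal_dunn,
    kruskal_h_brute,
    report,
)

#: frozen oracle: H for {1,2,3} vs {101,102,103} by the exhaustive rank-sum
#: formula, 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) with ranks 1..6
H_TWO_GROUPS = 3.857142857142857


class TestKruskalDunn:
    def test_matches_brute_force_rank_formula(self):
        groups = {"lo": [1.0, 2.0, 3.0], "hi": [101.0, 102.0, 103.0]}
        assert kruskal_h_brute(groups) == pytest.approx(H_TWO_GROUPS, abs=1e-9)
        gc = kruskal_dunn(groups)
        assert gc.h_statistic == pytest.approx(H_TWO_GROUPS, abs=1e-9)
        assert gc.letters["lo"] != gc.letters["hi"]

    def test_identical_constant_groups_share_one_letter(self):
        gc = kruskal_dunn({"a": [5.0, 5.0], "b": [5.0, 5.0], "c": [5.0, 5.0]})
        assert gc.h_statistic == 0.0
        assert set(gc.letters.values()) == {"a"}

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            kruskal_dunn({"a": [1.0], "b": [1.0, 2.0]})

    def test_h_invariant_under_monotone_transform(self, rng):
        groups = {k: rng.normal(loc=i, size=12) for i, k in enumerate("abc")}
        h1 = kruskal_dunn(groups).h_statistic
        h2 = kruskal_dunn(
            {k: np.exp(v) + 3 for k, v in groups.items()}
        ).h_statistic
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_letters_reproduce_thresholded_p_matrix(self, rng):
        """Graph-theoretic consistency: two levels share a letter iff their
        adjusted p is >= alpha."""
        for trial in range(10):
            groups = {
                k: rng.normal(loc=rng.uniform(0, 3), size=8) for k in "abcde"
            }
            gc = kruskal_dunn(groups)
            padj = {
                frozenset((r.level_a, r.level_b)): r.p_adj
                for r in gc.pairwise.itertuples()
            }
            for x, y in itertools.combinations(gc.levels, 2):
                share = bool(set(gc.letters[x]) & set(gc.letters[y]))
                significant = padj[frozenset((x, y))] < gc.alpha
                assert share != significant

    def test_type_i_error_near_nominal(self, rng):
        """Under the global null the rejection rate at alpha 0.05 stays inside
        the binomial 95% envelope for 1000 simulations."""
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            groups = {k: rng.normal(size=10) for k in "abc"}
            if kruskal_dunn(groups).p_value < 0.05:
                rejections += 1
        assert 0.036 <= rejections / n_sim <= 0.064


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], set())
        assert set(letters.values()) == {"a"}

    def test_all_different_all_distinct(self):
        lv = ["a", "b", "c"]
        letters = compact_letter_display(
            lv, set(itertools.combinations(lv, 2))
        )
        assert len({letters[x] for x in lv}) == 3

    def test_chain_structure_shares_middle(self):
        # a differs from c only: b bridges both
        letters = compact_letter_display(["a", "b", "c"], {("a", "c")})
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestAnovaPartition:
    def test_single_factor_zero_noise_explains_everything(self):
        rows = [
            {"f": lvl, "y": float(val)}
            for lvl, val in [("a", 1.0), ("b", 2.0), ("c", 3.0)]
            for _ in range(4)
        ]
        vp = anova_partition(pd.DataFrame(rows), "y", ["f"])
        assert vp.fraction("f") == pytest.approx(100.0, abs=1e-6)

    def test_known_variance_components_recovered(self, rng):
        """Balanced two-factor design with component ratio 2:1:1 recovers a
        50/25/25 split within 5 points at 20 replicates per cell."""
        a_lv = b_lv = 5
        alpha = rng.normal(size=a_lv)
        alpha = (alpha - alpha.mean()) / alpha.std() * np.sqrt(2.0)
        beta = rng.normal(size=b_lv)
        beta = (beta - beta.mean()) / beta.std()
        rows = []
        for i in range(a_lv):
            for j in range(b_lv):
                for _ in range(20):
                    rows.append(
                        {
                            "dose": f"d{i}",
                            "strain": f"s{j}",
                            "y": alpha[i] + beta[j] + rng.normal(),
                        }
                    )
        vp = anova_partition(pd.DataFrame(rows), "y", ["dose", "strain"])
        assert vp.fraction("dose") == pytest.approx(50.0, abs=5.0)
        assert vp.fraction("strain") == pytest.approx(25.0, abs=5.0)
        assert vp.fraction("residual") == pytest.approx(25.0, abs=5.0)

    def test_fractions_sum_to_100_and_row_order_invariant(self, rng):
        rows = [
            {
                "dose": f"d{rng.integers(3)}",
                "strain": f"s{rng.integers(3)}",
                "y": float(rng.normal()),
            }
            for _ in range(90)
        ]
        df = pd.DataFrame(rows)
        vp1 = anova_partition(df, "y", ["dose", "strain"])
        assert vp1.table["fraction_pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert (vp1.table["fraction_pct"] >= 0).all()
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        vp2 = anova_partition(shuffled, "y", ["dose", "strain"])
        pd.testing.assert_frame_equal(
            vp1.table.reset_index(drop=True), vp2.table.reset_index(drop=True)
        )

    def test_interaction_terms_in_schema(self, rng):
        rows = [
            {
                "dose": f"d{i}",
                "strain": f"s{j}",
                "density": f"n{k}",
                "y": float(rng.normal() + i),
            }
            for i in range(3)
            for j in range(3)
            for k in range(2)
            for _ in range(3)
        ]
        vp = anova_partition(
            pd.DataFrame(rows),
            "y",
            ["dose", "strain", "density"],
            interactions=[("dose", "strain"), ("density", "dose")],
        )
        assert {"dose", "strain", "density", "dosexstrain", "densityxdose",
                "residual"} <= set(vp.terms)


class TestReport:
    def test_empty_comparisons_still_writes_tables(self, tmp_path):
        df = pd.DataFrame(
            {"dose": [0.0, 0.5], "amax_px": [1000, 600],
             "normalized_lag_days": ["0", "2"]}
        )
        summary = report(df, [], [], tmp_path)
        assert (tmp_path / "report.json").exists()
        assert summary["n_records"] == 2

    def test_full_report_letters_match_comparison(self, tmp_path, rng):
        rows = []
        for dose, mu in [(0.0, 2000), (0.5, 800)]:
            for i in range(12):
                rows.append(
                    {
                        "strain": f"s{i}",
                        "genetic_group": "A1",
                        "dose": dose,
                        "amax_px": float(rng.normal(mu, 50)),
                        "lag_days": "6",
                        "normalized_lag_days": f"{dose * 10:g}",
                    }
                )
        df = pd.DataFrame(rows)
        gc = kruskal_dunn(
            {f"{d:g}": g["amax_px"].to_numpy() for d, g in df.groupby("dose")}
        )
        summary = report(df, [gc], [], tmp_path)
        assert (tmp_path / "comparisons.csv").exists()
        assert summary["comparisons"][0]["letters"] == gc.letters
        assert (tmp_path / "amax_by_dose.png").exists()
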