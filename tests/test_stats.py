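"""Group-comparison statistics against textbook oracles."""

import numpy as np
import pandas as pd
import pytest

from punctacoloc import (
    kruskal_wallis,
    mann_whitney,
    one_way_anova,
    summarize_groups,
    two_way_anova,
)

from oracles import (
    kruskal_h_oracle,
    mannwhitney_exact_p_oracle,
    oneway_f_oracle,
    twoway_balanced_f_oracle,
)


def _oneway_table(groups: dict):
    return pd.DataFrame(
        [(g, v) for g, vals in groups.items() for v in vals],
        columns=["treatment", "y"],
    )


def _twoway_table(cells: dict):
    return pd.DataFrame(
        [(a, b, v) for (a, b), vals in cells.items() for v in vals],
        columns=["treatment", "stage", "y"],
    )


class TestTwoWayAnova:
    CELLS = {
        ("DMSO", "foraging"): np.array([3.0, 5.0, 4.0]),
        ("DMSO", "wandering"): np.array([6.0, 8.0, 7.0]),
        ("atRA", "foraging"): np.array([10.0, 9.0, 11.0]),
        ("atRA", "wandering"): np.array([12.0, 15.0, 14.0]),
    }

    def test_balanced_toy_matches_ss_oracle(self):
        report = two_way_anova(_twoway_table(self.CELLS), "y", "treatment", "stage")
        oracle = twoway_balanced_f_oracle(self.CELLS)
        assert report.statistics["F_treatment"] == pytest.approx(oracle["A"][0], rel=1e-9)
        assert report.statistics["F_stage"] == pytest.approx(oracle["B"][0], rel=1e-9)
        assert report.statistics["F_interaction"] == pytest.approx(oracle["AB"][0], rel=1e-9)
        assert report.df["treatment"] == (1.0, 8.0)

    def test_location_and_scale_invariance(self):
        base = two_way_anova(_twoway_table(self.CELLS), "y", "treatment", "stage")
        shifted = {k: v + 100.0 for k, v in self.CELLS.items()}
        scaled = {k: v * 3.5 for k, v in self.CELLS.items()}
        for variant in (shifted, scaled):
            rep = two_way_anova(_twoway_table(variant), "y", "treatment", "stage")
            for term in base.p_values:
                assert rep.statistics[f"F_{term}"] == pytest.approx(
                    base.statistics[f"F_{term}"], rel=1e-9
                )
                assert rep.p_values[term] == pytest.approx(base.p_values[term], rel=1e-9)

    def test_empty_cell_is_error(self):
        cells = {k: v for k, v in self.CELLS.items() if k != ("atRA", "wandering")}
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova(_twoway_table(cells), "y", "treatment", "stage")

    def test_single_level_factor_is_error(self):
        cells = {k: v for k, v in self.CELLS.items() if k[0] == "DMSO"}
        with pytest.raises(ValueError, match=">= 2 levels"):
            two_way_anova(_twoway_table(cells), "y", "treatment", "stage")

    def test_unbalanced_type2_runs_and_reduces_df(self):
        cells = dict(self.CELLS)
        cells[("DMSO", "foraging")] = np.array([3.0, 5.0, 4.0, 4.5, 3.5])
        report = two_way_anova(_twoway_table(cells), "y", "treatment", "stage")
        assert report.df["treatment"][1] == 10.0
        assert all(0 <= p <= 1 for p in report.p_values.values())


class TestOneWayAnova:
    GROUPS = {
        "DMSO": [1.0, 2.0, 1.5, 2.5],
        "atRA": [5.0, 6.0, 5.5, 6.5],
        "9cisRA": [5.2, 6.1, 5.4, 6.3],
    }

    def test_f_matches_ss_oracle(self):
        report = one_way_anova(_oneway_table(self.GROUPS), "y", "treatment")
        f, df1, df2 = oneway_f_oracle([np.asarray(v) for v in self.GROUPS.values()])
        assert report.statistics["F"] == pytest.approx(f, rel=1e-9)
        assert report.df["group"] == (df1, df2)

    def test_posthoc_bonferroni_cap_at_one(self):
        # two equivalent treated groups, one distinct control: their pairwise
        # adjusted p is capped at 1.0
        groups = {
            "DMSO": [1.0, 1.2, 0.9, 1.1],
            "atRA": [5.0, 5.2, 4.9, 5.1],
            "9cisRA": [5.0, 5.2, 4.9, 5.1],
        }
        report = one_way_anova(_oneway_table(groups), "y", "treatment")
        assert report.p_values["group"] <= 0.05
        ph = report.posthoc.set_index(["group_a", "group_b"])
        assert ph.loc[("9cisRA", "atRA"), "p_adj"] == 1.0

    def test_posthoc_adjustment_is_m_times_raw(self):
        report = one_way_anova(_oneway_table(self.GROUPS), "y", "treatment")
        m = len(report.posthoc)
        assert m == 3
        for _, row in report.posthoc.iterrows():
            assert row["p_adj"] == pytest.approx(min(1.0, m * row["p_raw"]))

    def test_small_group_is_error(self):
        groups = {"a": [1.0], "b": [2.0, 3.0]}
        with pytest.raises(ValueError, match="n = 1"):
            one_way_anova(_oneway_table(groups), "y", "treatment")


class TestKruskalWallis:
    def test_h_matches_rank_formula_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        report = kruskal_wallis(_oneway_table(groups), "y", "treatment")
        h = kruskal_h_oracle([np.asarray(v) for v in groups.values()])
        assert report.statistics["H"] == pytest.approx(h, rel=1e-12)

    def test_tied_data_matches_oracle(self, rng):
        for _ in range(10):
            groups = {
                g: rng.integers(0, 5, size=8).astype(float)
                for g in ("a", "b", "c")
            }
            report = kruskal_wallis(_oneway_table(groups), "y", "treatment")
            h = kruskal_h_oracle([np.asarray(v) for v in groups.values()])
            assert report.statistics["H"] == pytest.approx(h, rel=1e-9)

    def test_degenerate_all_equal(self):
        groups = {"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]}
        report = kruskal_wallis(_oneway_table(groups), "y", "treatment")
        assert report.statistics["H"] == 0.0
        assert report.p_values["group"] == 1.0

    def test_relabeling_invariance(self, rng):
        vals = rng.normal(size=12)
        labels = np.repeat(["a", "b", "c"], 4)
        t1 = pd.DataFrame({"treatment": labels, "y": vals})
        perm = rng.permutation(12)
        t2 = pd.DataFrame({"treatment": labels[perm], "y": vals[perm]})
        r1 = kruskal_wallis(t1, "y", "treatment")
        r2 = kruskal_wallis(t2, "y", "treatment")
        assert r1.statistics["H"] == pytest.approx(r2.statistics["H"], rel=1e-12)

    def test_dunn_posthoc_emitted_on_significance(self, rng):
        groups = {
            "a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
            "c": rng.normal(5, 1, 15),
        }
        report = kruskal_wallis(_oneway_table(groups), "y", "treatment")
        assert report.p_values["group"] <= 0.05
        assert len(report.posthoc) == 3
        assert ((report.posthoc["p_adj"] >= 0) & (report.posthoc["p_adj"] <= 1)).all()

    def test_two_group_kw_consistent_with_mann_whitney(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.8, 1, 25)
        kw = kruskal_wallis(
            pd.DataFrame({"g": ["x"] * 25 + ["y"] * 25, "y": np.concatenate([x, y])}),
            "y", "g",
        )
        mw = mann_whitney(x, y)
        assert kw.p_values["group"] == pytest.approx(mw.p_values["U"], abs=0.02)


class TestMannWhitney:
    def test_identical_samples(self):
        report = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert report.statistics["U"] == 4.5  # n1*n2/2
        assert report.p_values["U"] == 1.0

    def test_fully_separated_small_samples_exact(self):
        report = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert report.statistics["U"] == 0.0
        assert report.p_values["U"] == pytest.approx(0.1)  # 2 / C(6,3)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(1.0, 9.0))  # tie-free n1 = n2 = 4
        x, y = vals[:4], vals[4:]
        report = mann_whitney(x, y)
        u, p = mannwhitney_exact_p_oracle(x, y)
        assert report.statistics["U"] == pytest.approx(u)
        assert report.p_values["U"] == pytest.approx(p, rel=1e-12)

    def test_power_with_two_sd_shift(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0, 1, 15)
            y = rng.normal(2, 1, 15)
            if mann_whitney(x, y).p_values["U"] <= 0.05:
                rejections += 1
        assert rejections / n_rep > 0.95


class TestSummaries:
    def test_hand_arithmetic(self):
        table = pd.DataFrame({"g": ["a"] * 3, "y": [2.0, 4.0, 6.0]})
        (s,) = summarize_groups(table, "y", "g")
        assert s.n == 3
        assert s.mean == 4.0
        assert s.sem == pytest.approx(2.0 / np.sqrt(3))

    def test_single_value_sem_missing(self):
        table = pd.DataFrame({"g": ["a"], "y": [5.0]})
        (s,) = summarize_groups(table, "y", "g")
        assert s.sem is None

    def test_undefined_values_dropped_from_n(self):
        table = pd.DataFrame({"g": ["a"] * 3, "y": [1.0, np.nan, 3.0]})
        (s,) = summarize_groups(table, "y", "g")
        assert s.n == 2
        assert s.mean == 2.0
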