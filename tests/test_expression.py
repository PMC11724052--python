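"""Count normalisation, the NB Wald test, shrinkage, BH adjustment and the
terminal-U Fisher overlay."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tailcomp import expression as E


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3],
                               "c": [5, 10, 3]})
        np.testing.assert_allclose(E.size_factors(counts), 1.0)

    def test_doubling_a_column_doubles_its_relative_factor(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3]})
        doubled = counts.assign(b=counts["b"] * 2)
        sf0 = E.size_factors(counts)
        sf1 = E.size_factors(doubled)
        ratio = (sf1["b"] / sf1["a"]) / (sf0["b"] / sf0["a"])
        assert ratio == pytest.approx(2.0)

    def test_two_gene_hand_example(self):
        counts = pd.DataFrame([[2, 4], [8, 16]], columns=["a", "b"])
        sf = E.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_no_all_positive_gene_rejected(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError):
            E.size_factors(counts)


class TestNbWaldTest:
    def test_single_condition_rejected(self):
        counts, cond = E.simulate_counts(n_genes=50, seed=0)
        with pytest.raises(ValueError):
            E.nb_wald_test(counts, pd.Series("A", index=cond.index))

    def test_too_few_replicates_rejected(self):
        counts, _ = E.simulate_counts(n_genes=50, n_per_condition=2, seed=0)
        cond = pd.Series(["A", "A", "A", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            E.nb_wald_test(counts, cond)

    def test_identical_counts_give_zero_lfc(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 200, size=60)
        counts = pd.DataFrame({f"{c}_rep{j}": col for c in "AB"
                               for j in range(1, 4)})
        cond = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        res = E.nb_wald_test(counts, cond)
        np.testing.assert_allclose(res["log2fc_raw"], 0.0, atol=1e-9)

    def test_all_zero_genes_excluded(self):
        counts, cond = E.simulate_counts(n_genes=100, seed=2)
        counts.iloc[3] = 0
        res = E.nb_wald_test(counts, cond)
        assert "gene_0003" not in res.index

    def test_null_false_positive_fraction(self):
        fractions = []
        for seed in (1, 2):
            counts, cond = E.simulate_counts(n_genes=2000, n_per_condition=3,
                                             dispersion=0.1, seed=seed)
            res = E.nb_wald_test(counts, cond)
            fractions.append(float((res["p_value"] < 0.05).mean()))
        assert 0.03 <= np.mean(fractions) <= 0.08

    def test_planted_fold_changes_recovered(self):
        de = {f"gene_{i:04d}": 2.0 for i in range(100)}
        counts, cond = E.simulate_counts(n_genes=2000, de_genes=de, seed=9)
        res = E.nb_wald_test(counts, cond)
        med = res.loc[list(de), "log2fc_raw"].abs().median()
        assert abs(med - 2.0) <= 0.5

    def test_padj_dominates_p(self):
        counts, cond = E.simulate_counts(n_genes=500, seed=4)
        res = E.nb_wald_test(counts, cond)
        assert (res["padj"] >= res["p_value"] - 1e-12).all()
        assert res["padj"].between(0, 1).all()


class TestShrinkage:
    def test_zero_raw_gives_zero_shrunk(self):
        df = pd.DataFrame({"log2fc_raw": [0.0, 1.0], "lfc_se": [0.5, 0.5]})
        out = E.shrink_lfc(df)
        assert out["log2fc_shrunk"].iloc[0] == 0.0

    def test_contraction_everywhere(self):
        counts, cond = E.simulate_counts(n_genes=800, seed=5)
        res = E.nb_wald_test(counts, cond)
        assert (res["log2fc_shrunk"].abs()
                <= res["log2fc_raw"].abs() + 1e-12).all()

    def test_low_count_gene_shrinks_more(self):
        df = pd.DataFrame({"log2fc_raw": [1.0, 1.0, 0.2, -0.3],
                           "lfc_se": [0.1, 1.0, 0.4, 0.4]})
        out = E.shrink_lfc(df)
        high = out["log2fc_shrunk"].iloc[0] / 1.0
        low = out["log2fc_shrunk"].iloc[1] / 1.0
        assert high > low


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(E.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert E.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(E.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            E.bh_adjust([0.5, 1.2])

    @staticmethod
    def _brute_force_bh(p):
        """Independent step-up oracle."""
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, p[idx] * m / rank)
            adj[idx] = prev
        return adj

    def test_matches_oracle_on_all_subsets(self):
        base = [0.001, 0.04, 0.2, 0.5, 0.8, 0.96]
        for r in range(1, 7):
            for subset in itertools.combinations(base, r):
                np.testing.assert_allclose(
                    E.bh_adjust(list(subset)),
                    self._brute_force_bh(np.array(subset)), atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_oracle_on_random_vectors(self, p):
        np.testing.assert_allclose(E.bh_adjust(p),
                                   self._brute_force_bh(np.array(p)),
                                   atol=1e-12)


class TestTerminalUOverlay:
    def _results(self, padj, lfc):
        n = len(padj)
        return pd.DataFrame({"base_mean": 100.0, "log2fc_raw": lfc,
                             "lfc_se": 0.3, "p_value": padj, "padj": padj,
                             "log2fc_shrunk": lfc},
                            index=[f"g{i}" for i in range(n)])

    def test_hand_odds_ratio(self):
        padj = [0.01] * 8 + [0.5] * 2 + [0.01] * 10 + [0.5] * 40
        lfc = [-1.0] * 8 + [-1.0] * 2 + [-1.0] * 10 + [1.0] * 40
        res = self._results(padj, lfc)
        _, enr = E.terminal_u_overlay(res, [f"g{i}" for i in range(10)])
        assert enr["table"] == ((8, 2), (10, 40))
        assert enr["odds_ratio"] == pytest.approx(16.0)

    def test_empty_flag_set_gives_na(self):
        res = self._results([0.01] * 5, [-1.0] * 5)
        out, enr = E.terminal_u_overlay(res, [])
        assert not out["flag_terminal_U"].any()
        assert np.isnan(enr["odds_ratio"])

    def test_degenerate_table_capped_with_exact_p(self):
        padj = [0.01] * 5 + [0.5] * 5
        lfc = [-1.0] * 5 + [1.0] * 5
        res = self._results(padj, lfc)
        _, enr = E.terminal_u_overlay(res, [f"g{i}" for i in range(5)])
        assert enr["odds_ratio"] == E.ODDS_RATIO_CAP
        assert 0.0 < enr["p_value"] <= 1.0

    def test_random_flags_center_log_odds_at_zero(self):
        de = {f"gene_{i:04d}": -2.0 for i in range(0, 400, 2)}
        counts, cond = E.simulate_counts(n_genes=400, de_genes=de, seed=13)
        res = E.nb_wald_test(counts, cond)
        rng = np.random.default_rng(0)
        log_odds = []
        for _ in range(120):
            flags = rng.choice(res.index, size=80, replace=False)
            _, enr = E.terminal_u_overlay(res, flags)
            if np.isfinite(enr["odds_ratio"]) and enr["odds_ratio"] > 0:
                log_odds.append(np.log(enr["odds_ratio"]))
        assert abs(np.mean(log_odds)) < 0.25

    def test_joint_simulation_recovers_direction(self):
        good = 0
        for i in range(12):
            enr = E.joint_terminal_de_replicate(seed=500 + i)
            good += enr["odds_ratio"] > 1 and enr["p_value"] < 0.05
        assert good >= 11
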