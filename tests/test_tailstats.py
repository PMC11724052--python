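"""Composition summaries, positional profiles, the terminal-enrichment
permutation test and replicate-concordance matrices."""

import numpy as np
import pandas as pd
import pytest

import tailcomp as tc
from tailcomp import tailstats as T


def _class_data(rows):
    return pd.DataFrame(rows, columns=["readname", "class", "comments",
                                       "qc_tag", "polya_length"])


def _residue_data(rows):
    return pd.DataFrame(rows, columns=["readname", "prediction", "position",
                                       "polya_length", "confidence"])


class TestComposition:
    def test_all_blank_zero_frequencies(self):
        cd = _class_data([(f"r{i}", "blank", "none", "PASS", 100.0)
                          for i in range(5)])
        rd = _residue_data([])
        s = T.composition_frequencies(cd, rd)
        assert (s.freq_C, s.freq_G, s.freq_U) == (0.0, 0.0, 0.0)
        assert s.n_classified == 5

    def test_hand_counted_example(self):
        """10 classified reads, 2 carry only U (one of them twice), 1 carries C:
        freq_U = 0.2, freq_C = 0.1, instance shares over 3 instances."""
        cd = _class_data(
            [(f"r{i}", "blank", "none", "PASS", 100.0) for i in range(7)]
            + [("u1", "decorated", "", "PASS", 100.0),
               ("u2", "decorated", "", "PASS", 100.0),
               ("c1", "decorated", "", "PASS", 100.0)])
        rd = _residue_data([("u1", "U", 3, 100.0, 0.9),
                            ("u2", "U", 5, 100.0, 0.9),
                            ("c1", "C", 9, 100.0, 0.9)])
        s = T.composition_frequencies(cd, rd)
        assert s.n_classified == 10
        assert s.freq_U == pytest.approx(0.2)
        assert s.freq_C == pytest.approx(0.1)
        assert (s.residue_share_C, s.residue_share_G, s.residue_share_U) == \
            pytest.approx((1 / 3, 0.0, 2 / 3))

    def test_only_classified_reads_counted(self):
        cd = _class_data([("a", "blank", "", "PASS", 90.0),
                          ("b", "qc_failed", "", "NOREGION", np.nan),
                          ("c", "move_issue", "", "PASS", 80.0)])
        s = T.composition_frequencies(cd, _residue_data([]))
        assert s.n_classified == 1

    def test_empty_classified_warns_and_gives_na(self):
        cd = _class_data([("a", "qc_failed", "", "NOREGION", np.nan)])
        with pytest.warns(UserWarning):
            s = T.composition_frequencies(cd, _residue_data([]))
        assert np.isnan(s.freq_C)

    def test_gene_set_restriction(self):
        cd = _class_data([("a", "decorated", "", "PASS", 100.0),
                          ("b", "blank", "", "PASS", 100.0)])
        rd = _residue_data([("a", "U", 2, 100.0, 0.9)])
        s = T.composition_frequencies(cd, rd, gene_set={"tx1"},
                                      read_transcripts={"a": "tx1", "b": "tx2"})
        assert s.n_classified == 1
        assert s.freq_U == 1.0

    def test_simulated_shares_recover_weights(self, model, bench_sample,
                                              bench_detection):
        """Testis-like mix (U 0.6, C 0.25, G 0.15) recovered through the full
        simulate -> segment -> detect -> summarise chain."""
        class_data, residue_data = bench_detection
        s = T.composition_frequencies(class_data, residue_data)
        n = max(len(residue_data), 1)
        for base, w in (("C", 0.25), ("G", 0.15), ("U", 0.60)):
            share = getattr(s, f"residue_share_{base}")
            assert abs(share - w) <= 3 * np.sqrt(w * (1 - w) / n) + 0.02


class TestPositionalProfile:
    def test_single_call_single_point(self):
        rd = _residue_data([("r1", "U", 2, 50.0, 0.9)])
        prof = T.positional_profile(rd, "tx1", {"r1": "tx1"})
        assert len(prof.points) == 1
        assert tuple(prof.points.iloc[0][["position_nt", "polya_length_nt"]]) \
            == (2, 50.0)

    def test_point_count_matches_rows(self, bench_sample, bench_detection):
        _, residue_data = bench_detection
        read_tx = {r.read_id: r.transcript_id for r in bench_sample["reads"]}
        tx = bench_sample["reads"][0].transcript_id
        prof = T.positional_profile(residue_data, tx, read_tx)
        expected = residue_data["readname"].map(read_tx).eq(tx).sum()
        assert len(prof.points) == expected

    def test_unknown_transcript_flagged(self):
        prof = T.positional_profile(_residue_data([]), "nope", {"r": "tx"})
        assert prof.flag == "unknown_transcript"
        assert len(prof.points) == 0


class TestTerminalEnrichment:
    def test_all_calls_at_position_one(self):
        prof = T.PositionalProfile("tx", pd.DataFrame({
            "position_nt": [1] * 20, "polya_length_nt": [100.0] * 20,
            "base": ["U"] * 20}), 20)
        stat, p = T.terminal_enrichment_test(prof, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert stat == pytest.approx(0.01)

    def test_below_min_calls_declined(self):
        prof = T.PositionalProfile("tx", pd.DataFrame({
            "position_nt": [1] * 9, "polya_length_nt": [100.0] * 9,
            "base": ["U"] * 9}), 9)
        stat, p = T.terminal_enrichment_test(prof, min_calls=10)
        assert np.isnan(stat) and np.isnan(p)

    def test_type_one_error_roughly_nominal(self):
        rng = np.random.default_rng(8)
        rej = 0
        n = 150
        for i in range(n):
            L = rng.integers(50, 200, size=15)
            pos = rng.integers(1, L + 1)
            prof = T.PositionalProfile("tx", pd.DataFrame({
                "position_nt": pos, "polya_length_nt": L.astype(float),
                "base": "U"}), 15)
            _, p = T.terminal_enrichment_test(prof, n_perm=499, seed=100 + i)
            rej += p < 0.05
        assert 0.01 <= rej / n <= 0.11

    def test_power_under_strong_terminal_bias(self):
        rng = np.random.default_rng(9)
        rej = 0
        for i in range(40):
            L = rng.integers(50, 200, size=50)
            pos = np.minimum(rng.integers(1, np.maximum(L // 10, 1) + 1), L)
            prof = T.PositionalProfile("tx", pd.DataFrame({
                "position_nt": pos, "polya_length_nt": L.astype(float),
                "base": "U"}), 50)
            _, p = T.terminal_enrichment_test(prof, n_perm=499, seed=300 + i)
            rej += p < 0.05
        assert rej / 40 >= 0.95


class TestConcordance:
    def test_self_correlation_is_one(self):
        s = pd.DataFrame({"transcript_id": list("abcd"), "count": [1, 5, 2, 9]})
        mat = T.concordance_matrix({"x": s, "y": s.copy()})
        assert mat.loc["x", "y"] == pytest.approx(1.0)
        assert (np.diag(mat) == 1.0).all()

    def test_rank_reversal_gives_minus_one(self):
        s1 = pd.DataFrame({"transcript_id": list("abcd"), "count": [1, 2, 3, 4]})
        s2 = pd.DataFrame({"transcript_id": list("abcd"), "count": [4, 3, 2, 1]})
        mat = T.concordance_matrix({"x": s1, "y": s2})
        assert mat.loc["x", "y"] == pytest.approx(-1.0)

    def test_monotone_counts_give_rho_one(self):
        s1 = pd.DataFrame({"transcript_id": list("abc"), "count": [1, 2, 3]})
        s2 = pd.DataFrame({"transcript_id": list("abc"), "count": [10, 20, 30]})
        mat = T.concordance_matrix({"x": s1, "y": s2})
        assert mat.loc["x", "y"] == pytest.approx(1.0)

    def test_insufficient_overlap_gives_na(self):
        s1 = pd.DataFrame({"transcript_id": ["a", "b", "c"], "count": [1, 2, 3]})
        s2 = pd.DataFrame({"transcript_id": ["a", "x", "y"], "count": [1, 2, 3]})
        mat = T.concordance_matrix({"x": s1, "y": s2})
        assert np.isnan(mat.loc["x", "y"])

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        frames = {f"s{i}": pd.DataFrame({
            "transcript_id": list("abcdefgh"),
            "count": rng.integers(1, 100, 8)}) for i in range(3)}
        mat = T.concordance_matrix(frames)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_bad_metric_rejected(self):
        with pytest.raises(ValueError):
            T.concordance_matrix({}, metric="medians")


class TestTagFrequencies:
    def test_all_pass_sample(self):
        from tailcomp.segment import TailSegmentation
        segs = [TailSegmentation(read_id=f"r{i}", qc_tag="PASS")
                for i in range(4)]
        df = T.tag_frequency_summary({"s": segs})
        assert df.iloc[0]["PASS"] == 1.0
        assert df.iloc[0][["SUFFCLIP", "ADAPTER", "NOREGION",
                           "READ_FAILED_LOAD"]].sum() == 0.0

    def test_fractions_sum_to_one(self, bench_sample):
        df = T.tag_frequency_summary({"bench": bench_sample["segmentations"]})
        from tailcomp.segment import QC_TAGS
        assert df[list(QC_TAGS)].sum(axis=1).iloc[0] == pytest.approx(1.0)

    def test_hand_counts(self):
        from tailcomp.segment import TailSegmentation
        segs = [TailSegmentation(read_id="a", qc_tag="PASS"),
                TailSegmentation(read_id="b", qc_tag="PASS"),
                TailSegmentation(read_id="c", qc_tag="NOREGION"),
                TailSegmentation(read_id="d", qc_tag="ADAPTER")]
        df = T.tag_frequency_summary({"s": segs})
        assert df.iloc[0]["PASS"] == pytest.approx(0.5)
        assert df.iloc[0]["NOREGION"] == pytest.approx(0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            T.tag_frequency_summary({"s": []})
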