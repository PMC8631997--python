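"""Predictive-ability scoring and Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from vwpa.preprocess import TimingConfig, apply_pointing_exclusion, \
    bin_fixations, make_windows
from vwpa.simulate import SyntheticConfig, generate_vwp_dataset
from vwpa.vocab import (correlation_report, predictive_ability,
                        spearman_correlation, total_vocabulary)

WINDOWS = make_windows(TimingConfig())


def _bins(participant, condition, item, n_target, bin_start=3800,
          n_distractor=0):
    return {
        "participant_id": participant, "session_language": "norwegian",
        "condition": condition, "item_id": item, "bin_start_ms": bin_start,
        "n_target": n_target, "n_distractor": n_distractor,
        "n_fixpic": 0, "n_other": 0,
    }


def _hand_built_bins():
    rows = []
    # constraining: 120 target samples over 4 trials; neutral: 80 over 4
    for j in range(4):
        rows.append(_bins("p1", "constraining", f"c{j}", 30))
        rows.append(_bins("p1", "neutral", f"n{j}", 20))
    return pd.DataFrame(rows)


class TestPredictiveAbility:
    def test_hand_computed_per_trial_mean(self):
        scores = predictive_ability(_hand_built_bins(), WINDOWS,
                                    mode="per_trial_mean")
        assert scores["predictive_ability"].iloc[0] == pytest.approx(30 - 20)

    def test_identical_conditions_score_zero(self):
        rows = [_bins("p1", c, f"{c}{j}", 25) for c in
                ("constraining", "neutral") for j in range(3)]
        scores = predictive_ability(pd.DataFrame(rows), WINDOWS)
        assert scores["predictive_ability"].iloc[0] == 0.0

    def test_scaling_doubles_counts(self):
        bins = _hand_built_bins()
        doubled = bins.assign(n_target=bins["n_target"] * 2,
                              n_distractor=bins["n_distractor"] * 2)
        for mode, factor in (("per_trial_mean", 2.0), ("raw_count", 2.0),
                             ("proportion", 1.0)):
            s1 = predictive_ability(bins, WINDOWS, mode=mode)
            s2 = predictive_ability(doubled, WINDOWS, mode=mode)
            assert s2["predictive_ability"].iloc[0] == pytest.approx(
                factor * s1["predictive_ability"].iloc[0])

    def test_per_trial_mean_invariant_to_trial_count(self):
        """Identical per-trial behavior: adding trials leaves the score."""
        few = _hand_built_bins()
        more = pd.concat([few, pd.DataFrame(
            [_bins("p1", "constraining", "c9", 30),
             _bins("p1", "neutral", "n9", 20)])], ignore_index=True)
        s_few = predictive_ability(few, WINDOWS)
        s_more = predictive_ability(more, WINDOWS)
        assert s_few["predictive_ability"].iloc[0] == pytest.approx(
            s_more["predictive_ability"].iloc[0])

    def test_missing_condition_gives_undefined_score(self):
        rows = [_bins("p1", "constraining", "c1", 10)]
        scores = predictive_ability(pd.DataFrame(rows), WINDOWS)
        assert np.isnan(scores["predictive_ability"].iloc[0])

    def test_only_critical_window_bins_count(self):
        rows = [_bins("p1", "constraining", "c1", 10),
                _bins("p1", "constraining", "c1", 99, bin_start=5600),
                _bins("p1", "neutral", "n1", 4),
                _bins("p1", "neutral", "n1", 99, bin_start=3780)]
        scores = predictive_ability(pd.DataFrame(rows), WINDOWS)
        assert scores["predictive_ability"].iloc[0] == pytest.approx(10 - 4)


class TestTotalVocabulary:
    def test_plain_sum(self):
        vocab = pd.DataFrame({"participant_id": ["a", "b"],
                              "cdi_norwegian": [550, 0],
                              "cdi_english": [218, 0]})
        out = total_vocabulary(vocab)
        assert list(out["cdi_total"]) == [768, 0]

    def test_matches_brute_force_row_sums(self):
        rng = np.random.default_rng(1)
        vocab = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(30)],
            "cdi_norwegian": rng.integers(0, 680, 30),
            "cdi_english": rng.integers(0, 680, 30)})
        out = total_vocabulary(vocab)
        expected = [int(r.cdi_norwegian) + int(r.cdi_english)
                    for r in vocab.itertuples()]
        assert list(out["cdi_total"]) == expected

    def test_incomplete_row_flagged(self):
        vocab = pd.DataFrame({"participant_id": ["a"],
                              "cdi_norwegian": [300],
                              "cdi_english": [np.nan]})
        out = total_vocabulary(vocab)
        assert np.isnan(out["cdi_total"].iloc[0])


class TestSpearman:
    def test_monotone_identity(self):
        res = spearman_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.r == pytest.approx(1.0)

    def test_reversal(self):
        res = spearman_correlation([1, 2, 3], [3, 2, 1])
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        res = spearman_correlation([1, 1, 1], [1, 2, 3])
        assert res.r is None and res.p is None

    def test_too_few_points_undefined(self):
        res = spearman_correlation([1, 2], [2, 1])
        assert res.r is None

    @given(st.lists(st.integers(0, 8), min_size=4, max_size=25),
           st.data())
    def test_matches_rank_then_pearson_oracle_with_ties(self, xs, data):
        ys = data.draw(st.lists(st.integers(0, 8), min_size=len(xs),
                                max_size=len(xs)))
        x, y = np.array(xs, float), np.array(ys, float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        res = spearman_correlation(x, y)
        # brute-force oracle: mean ranks, then product-moment correlation
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_correlation(x, y).r
        assert spearman_correlation(np.exp(x), y).r == pytest.approx(base)
        assert spearman_correlation(x, y ** 3).r == pytest.approx(base)

    def test_exact_permutation_p_on_tiny_sample(self):
        res = spearman_correlation([1, 2, 3, 4, 5], [1, 2, 3, 4, 5],
                                   exact_permutation=True)
        # only the identity and the full reversal reach |r| = 1
        assert res.p == pytest.approx(2 / 120)


class TestCorrelationReport:
    def _scores_and_vocab(self, n=17, seed=0, coupled=False):
        rng = np.random.default_rng(seed)
        vocab = pd.DataFrame({
            "participant_id": [f"p{i:02d}" for i in range(n)],
            "cdi_norwegian": rng.integers(281, 664, n),
            "cdi_english": rng.integers(20, 565, n)})
        if coupled:
            ability = vocab["cdi_norwegian"] * 0.1 + rng.normal(0, 2, n)
        else:
            ability = rng.normal(10, 5, n)
        scores = pd.DataFrame({
            "participant_id": vocab["participant_id"],
            "session_language": "norwegian",
            "predictive_ability": ability})
        return scores, vocab

    def test_reports_four_pairs(self, tmp_path):
        scores, vocab = self._scores_and_vocab()
        eng = scores.assign(session_language="english")
        table = correlation_report(pd.concat([scores, eng]), vocab,
                                   out_dir=tmp_path)
        assert len(table) == 4
        assert set(table["pair"]) == {
            "predictive_norwegian_vs_cdi_norwegian",
            "predictive_norwegian_vs_cdi_total",
            "predictive_english_vs_cdi_english",
            "predictive_english_vs_cdi_total"}
        assert (tmp_path / "correlations_same_language.png").exists()

    def test_permuted_vocabulary_breaks_association(self):
        """Permutation null: the mean correlation over label permutations
        vanishes within Monte-Carlo error."""
        scores, vocab = self._scores_and_vocab(coupled=True)
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(200):
            perm = vocab.copy()
            perm["cdi_norwegian"] = rng.permutation(
                perm["cdi_norwegian"].to_numpy())
            r = spearman_correlation(scores["predictive_ability"],
                                     perm["cdi_norwegian"]).r
            rs.append(r)
        mc_se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 4 * mc_se + 0.02

    def test_fewer_than_three_cases_yields_none(self):
        scores, vocab = self._scores_and_vocab(n=2)
        table = correlation_report(scores, vocab)
        nor = table[table["pair"] == "predictive_norwegian_vs_cdi_norwegian"]
        assert nor["r"].iloc[0] is None or pd.isna(nor["r"].iloc[0])

    def test_vocabulary_onset_coupling_recovered_end_to_end(self):
        """Generator coupling rho = 0.8 between vocabulary and onset
        propagates into a clearly positive score-vocabulary correlation.

        The coupled channel is isolated: no participant preference noise and
        an onset SD of 300 ms, so the onset-variance signal dominates the
        per-trial binomial noise (at the study's own 150 ms onset SD the
        attainable correlation is capped near 0.45 by that noise).
        """
        rs = []
        for seed in (31, 32, 33):
            cfg = SyntheticConfig(seed=seed, n_participants=100,
                                  languages=("norwegian",),
                                  vocab_onset_corr=0.8,
                                  sigma_logit=0.0, sigma_onset_ms=300.0)
            samples, trials, vocab, _ = generate_vwp_dataset(cfg)
            retained, _ = apply_pointing_exclusion(trials)
            bins = bin_fixations(samples, retained, cfg.timing)
            scores = predictive_ability(bins, WINDOWS, trials=retained)
            table = correlation_report(scores, vocab)
            row = table[table["pair"]
                        == "predictive_norwegian_vs_cdi_norwegian"]
            rs.append(float(row["r"].iloc[0]))
        assert all(r > 0 for r in rs)
        assert np.median(rs) > 0.5
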