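"""Divergence-point estimation: null behavior, detection, summaries."""

import numpy as np
import pandas as pd
import pytest

from vwpa.divergence import (DivergencePointModel, estimate_divergence,
                             summarize_results, summary_from_estimates)
from vwpa.glmm import AnalysisConfig
from vwpa.preprocess import (TimingConfig, apply_pointing_exclusion,
                             bin_fixations, make_windows)
from vwpa.simulate import SyntheticConfig, generate_vwp_dataset

TIMING = TimingConfig()
PARTICIPANT_ONLY = AnalysisConfig(random_effects="participant")


def _flat_bins(n_participants=6, n_target=5, n_distractor=5):
    """Perfectly balanced counts in every bin of the extended window."""
    rows = []
    for b in range(3800, 7300, 20):
        for i in range(n_participants):
            rows.append({
                "participant_id": f"p{i}", "session_language": "norwegian",
                "condition": "constraining", "item_id": "i1",
                "bin_start_ms": b, "n_target": n_target,
                "n_distractor": n_distractor, "n_fixpic": 0, "n_other": 0,
            })
    return pd.DataFrame(rows)


def test_flat_chance_series_has_no_divergence():
    res = estimate_divergence(_flat_bins(), timing=TIMING,
                              config=PARTICIPANT_ONLY)
    assert res.divergence_ms_after_verb is None
    assert not res.in_critical_window
    assert res.z_at_divergence is None


def test_all_bins_of_extended_window_are_fitted():
    res = estimate_divergence(_flat_bins(), timing=TIMING,
                              config=PARTICIPANT_ONLY)
    assert len(res.bin_fits) == 175
    starts = [f.bin_start_ms for f in res.bin_fits]
    assert starts[0] == 3800 and starts[-1] == 7280


def test_fewer_than_two_participants_rejected():
    bins = _flat_bins(n_participants=1)
    with pytest.raises(ValueError, match="2 participants"):
        estimate_divergence(bins, timing=TIMING)


def test_mixed_cells_must_be_subset_first():
    bins = pd.concat([
        _flat_bins(),
        _flat_bins().assign(condition="neutral"),
    ])
    with pytest.raises(ValueError, match="subset"):
        DivergencePointModel(bins, timing=TIMING)
    res = estimate_divergence(bins, timing=TIMING, condition="neutral",
                              config=PARTICIPANT_ONLY)
    assert res.condition == "neutral"


def _analyze(cfg, condition="constraining", analysis=PARTICIPANT_ONLY):
    samples, trials, _, _ = generate_vwp_dataset(cfg)
    retained, _ = apply_pointing_exclusion(trials)
    bins = bin_fixations(samples, retained, cfg.timing)
    return estimate_divergence(bins, timing=cfg.timing, condition=condition,
                               config=analysis)


def test_step_onset_detected_at_the_step(strong_effect_dataset):
    """A sharp step to the asymptote at 1,000 ms after the verb is found in
    the bin that contains it (this seed: exactly)."""
    cfg = SyntheticConfig(seed=1, languages=("norwegian",),
                          sigma_onset_ms=0.0, ramp_rate_per_ms=1.0)
    res = _analyze(cfg)
    assert res.divergence_ms_after_verb == 1000.0
    assert res.in_critical_window
    assert res.p_adj_at_divergence < 0.05


def test_neutral_condition_diverges_near_noun_driven_onset(
        strong_effect_dataset):
    """Neutral trials carry no verb signal: the divergence sits near the
    noun-driven onset (2,100 ms after the verb), far from the constraining
    condition's 1,000 ms.  min_run=2 suppresses isolated null bins that the
    BH step-up can promote once many later bins are strongly significant;
    mean-zero participant onset jitter can genuinely advance the population
    curve by a bin or two."""
    cfg, (samples, trials, _, _) = strong_effect_dataset
    retained, _ = apply_pointing_exclusion(trials)
    bins = bin_fixations(samples, retained, cfg.timing)
    res = estimate_divergence(
        bins, timing=cfg.timing, condition="neutral",
        config=AnalysisConfig(random_effects="participant", min_run=2))
    assert res.divergence_ms_after_verb is not None
    assert 1900 <= res.divergence_ms_after_verb <= 2300


def test_divergence_estimate_tracks_the_true_onset():
    """Shifting the synthetic onset later moves the estimate by about the
    same amount (min_run=2 suppresses isolated false bins so the location
    property is visible)."""
    analysis = AnalysisConfig(random_effects="participant", min_run=2)
    est = {}
    for onset in (1000.0, 1400.0):
        cfg = SyntheticConfig(
            seed=77, languages=("norwegian",), sigma_onset_ms=0.0,
            ramp_rate_per_ms=1.0,
            true_onset_after_verb_ms=(("constraining", onset),
                                      ("neutral", 2100.0)))
        est[onset] = _analyze(cfg, analysis=analysis).divergence_ms_after_verb
    assert est[1400.0] - est[1000.0] == pytest.approx(400.0, abs=60.0)


def test_bonferroni_adjustment_dominates_fdr():
    cfg = SyntheticConfig(seed=13, n_participants=6, languages=("norwegian",))
    samples, trials, _, _ = generate_vwp_dataset(cfg)
    retained, _ = apply_pointing_exclusion(trials)
    bins = bin_fixations(samples, retained, cfg.timing)
    out = {}
    for correction in ("fdr", "bonferroni"):
        res = estimate_divergence(
            bins, timing=cfg.timing, condition="constraining",
            config=AnalysisConfig(random_effects="participant",
                                  correction=correction))
        out[correction] = np.array([f.p_adj for f in res.bin_fits])
    assert (out["bonferroni"] >= out["fdr"] - 1e-12).all()


def test_summary_of_table_style_estimates():
    # published-style constraining estimates: 1,020 (norwegian) and
    # 1,620 (english) -> between-language difference 600 ms
    table = summary_from_estimates({
        ("constraining", "norwegian"): 1020.0,
        ("constraining", "english"): 1620.0,
        ("neutral", "norwegian"): 2720.0,
        ("neutral", "english"): 2960.0,
    })
    con = table[table["condition"] == "constraining"].iloc[0]
    neu = table[table["condition"] == "neutral"].iloc[0]
    assert con["difference_ms"] == 600.0
    assert neu["difference_ms"] == 240.0


def test_summary_difference_is_elementwise_subtraction():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.integers(0, 3500, 2) // 20 * 20
        table = summary_from_estimates({
            ("constraining", "norwegian"): float(a),
            ("constraining", "english"): float(b)})
        assert table["difference_ms"].iloc[0] == float(b - a)
    equal = summary_from_estimates({
        ("constraining", "norwegian"): 1000.0,
        ("constraining", "english"): 1000.0})
    assert equal["difference_ms"].iloc[0] == 0.0


def test_summarize_results_runs_on_fitted_models():
    bins = pd.concat([
        _flat_bins(),
        _flat_bins().assign(session_language="english"),
    ])
    results = [
        estimate_divergence(bins, timing=TIMING, session_language=lang,
                            condition="constraining", config=PARTICIPANT_ONLY)
        for lang in ("norwegian", "english")
    ]
    table = summarize_results(results)
    assert len(table) == 1
    assert np.isnan(table["difference_ms"].iloc[0])  # no divergence anywhere


def test_results_summary_text_mentions_estimate(strong_effect_dataset):
    cfg, (samples, trials, _, _) = strong_effect_dataset
    retained, _ = apply_pointing_exclusion(trials)
    bins = bin_fixations(samples, retained, cfg.timing)
    res = estimate_divergence(bins, timing=cfg.timing,
                              condition="constraining",
                              config=PARTICIPANT_ONLY)
    text = res.summary()
    assert "divergence point" in text
    assert "ms after verb onset" in text
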