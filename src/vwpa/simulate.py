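"""Synthetic visual-world-paradigm datasets with known ground truth.

The generator emulates the study design the analysis assumes: 17 children,
two session languages, 14 trials per session (7 with a semantically
constraining verb, 7 with a neutral verb), 250 Hz sampling over 8-second
trials with the verb at 3,500 ms and the noun at 5,300 ms, and parent-
reported CDI vocabulary scores.

Per sample, the AOI is drawn from a time-varying categorical distribution:
the fixation-picture probability starts high (the pictures preview plus the
subject-first context sentence pull gaze to the top) and decays after audio
onset; a small constant share lands outside every picture; the remaining
mass is split between target and distractor with p_target(t).  p_target
stays at baseline (0.5) until the participant-specific effect onset
(condition's true onset + a participant shift), then follows a logistic
ramp to the asymptote; in the neutral condition the onset defaults to noun
onset + saccade latency, i.e. prediction is absent and only noun-driven
orienting occurs.  A per-participant preference term on the log-odds scale
adds stable individual bias.  Trials flagged as incorrectly pointed are
generated with no target preference at all.

Draws are i.i.d. across samples given the probabilities — no gaze
persistence; an optional first-order stickiness parameter exists for
sensitivity checks.  Each participant consumes an independent random
stream spawned from the master seed, so adding participants never perturbs
existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as vio
from .preprocess import TimingConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study design."""

    seed: int
    n_participants: int = 17
    trials_per_condition_per_language: int = 7
    languages: tuple[str, ...] = ("norwegian", "english")
    trial_duration_ms: int = 8000
    timing: TimingConfig = field(default_factory=TimingConfig)
    # effect onset, ms after verb onset, per condition
    true_onset_after_verb_ms: tuple[tuple[str, float], ...] = (
        ("constraining", 1000.0),
        ("neutral", 2100.0),  # = noun - verb + saccade latency: no prediction
    )
    ramp_rate_per_ms: float = 0.01
    asymptote_p_target: float = 0.85
    baseline_p_target: float = 0.5
    p_fixpic_initial: float = 0.7
    p_fixpic_floor: float = 0.1
    fixpic_decay_tau_ms: float = 1500.0
    p_other_aoi: float = 0.05
    p_saccade: float = 0.10
    p_event_other: float = 0.05
    sigma_onset_ms: float = 150.0
    sigma_logit: float = 0.3
    stickiness: float = 0.0  # optional first-order gaze persistence
    pointing_error_rate: float = 0.09
    cdi_norwegian_mean: float = 549.41
    cdi_norwegian_sd: float = 95.54
    cdi_english_mean: float = 217.56
    cdi_english_sd: float = 156.97
    vocab_onset_corr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("asymptote_p_target", "baseline_p_target",
                     "p_fixpic_initial", "p_fixpic_floor", "p_other_aoi",
                     "p_saccade", "p_event_other", "pointing_error_rate",
                     "stickiness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("sigma_onset_ms", "sigma_logit", "cdi_norwegian_sd",
                     "cdi_english_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.vocab_onset_corr <= 1.0:
            raise ValueError("vocab_onset_corr must lie in [-1, 1]")
        if self.asymptote_p_target < self.baseline_p_target:
            logger.warning(
                "asymptote below baseline: target preference will decrease; "
                "a positive-direction analysis will not detect it"
            )

    @property
    def onsets(self) -> dict[str, float]:
        return dict(self.true_onset_after_verb_ms)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timing"] = dataclasses.asdict(self.timing)
        d["true_onset_after_verb_ms"] = dict(self.true_onset_after_verb_ms)
        d["languages"] = list(self.languages)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset (for recovery tests)."""

    config: dict
    onset_shift_ms: dict          # (participant, language) -> shift
    preference_logit: dict        # (participant, language) -> bias
    true_onset_after_verb_ms: dict  # condition -> nominal onset
    pointed_correct: dict         # (participant, language, trial) -> bool
    realized_pointing_error_rate: float

    def to_json(self, path) -> Path:
        path = Path(path)

        def _keyed(d):
            return {"|".join(map(str, k)): v for k, v in d.items()}

        payload = {
            "config": self.config,
            "onset_shift_ms": _keyed(self.onset_shift_ms),
            "preference_logit": _keyed(self.preference_logit),
            "true_onset_after_verb_ms": self.true_onset_after_verb_ms,
            "pointed_correct": _keyed(self.pointed_correct),
            "realized_pointing_error_rate": self.realized_pointing_error_rate,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return path


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(seed, spawn_key=(index,))))


def _draw_cdi(rng, mean, sd) -> tuple[int, float]:
    """Truncated-at-zero normal draw; returns (count, standard-normal z)."""
    for _ in range(1000):
        z = rng.standard_normal()
        value = mean + sd * z
        if value >= 0:
            return int(round(value)), z
    return 0, 0.0


def p_target_curve(t_ms: np.ndarray, onset_abs_ms: float,
                   config: SyntheticConfig) -> np.ndarray:
    """Generating p_target(t): baseline, then a logistic ramp to asymptote."""
    t = np.asarray(t_ms, dtype=float)
    ramp = np.zeros_like(t)
    after = t >= onset_abs_ms
    arg = config.ramp_rate_per_ms * (t[after] - onset_abs_ms)
    ramp[after] = 2.0 * expit(arg) - 1.0
    return config.baseline_p_target + (
        config.asymptote_p_target - config.baseline_p_target) * ramp


def p_fixpic_curve(t_ms: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Fixation-picture attraction: high during preview, decaying after audio."""
    t = np.asarray(t_ms, dtype=float)
    audio = config.timing.audio_onset_ms
    init, floor = config.p_fixpic_initial, config.p_fixpic_floor
    out = np.full_like(t, init)
    after = t >= audio
    out[after] = floor + (init - floor) * np.exp(
        -(t[after] - audio) / config.fixpic_decay_tau_ms)
    return out


def generate_vwp_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (SampleTable, TrialTable, VocabTable, SyntheticTruth)."""
    timing = config.timing
    step = 1000 // timing.sample_rate_hz
    if step * timing.sample_rate_hz != 1000:
        raise ValueError("sample_rate_hz must divide 1000")
    t_grid = np.arange(0, config.trial_duration_ms, step, dtype=np.int64)
    n_per_cond = config.trials_per_condition_per_language
    n_trials = 2 * n_per_cond
    onsets = config.onsets

    # categorical AOI levels in draw order: fixpic, other, target, distractor
    aoi_levels = ["fixation_picture", "other", "target", "distractor"]
    event_levels = ["other", "saccade", "fixation"]
    pid_levels = [f"p{i + 1:02d}" for i in range(config.n_participants)]
    trial_levels = [f"t{pos:02d}" for pos in range(1, n_trials + 1)]
    lang_levels = list(config.languages)
    p_fix = p_fixpic_curve(t_grid, config) * (1.0 - config.p_other_aoi)
    p_oth = config.p_other_aoi
    rest = 1.0 - p_fix - p_oth

    col_pid, col_lang, col_trial, col_aoi, col_event = [], [], [], [], []
    trial_rows = []
    vocab_rows = []
    shifts: dict = {}
    prefs: dict = {}
    pointed: dict = {}

    for i in range(config.n_participants):
        pid = f"p{i + 1:02d}"
        rng = _participant_rng(config.seed, i)
        cdi: dict[str, int] = {}
        for lang in ("norwegian", "english"):
            mean = getattr(config, f"cdi_{lang}_mean")
            sd = getattr(config, f"cdi_{lang}_sd")
            count, z_cdi = _draw_cdi(rng, mean, sd)
            cdi[lang] = count
            rho = config.vocab_onset_corr
            eps = rng.standard_normal()
            # larger same-language vocabulary -> earlier onset when coupled
            shift = config.sigma_onset_ms * (
                -rho * z_cdi + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps)
            shifts[(pid, lang)] = float(shift)
            prefs[(pid, lang)] = float(rng.normal(0.0, config.sigma_logit))
        vocab_rows.append({"participant_id": pid,
                           "cdi_norwegian": cdi["norwegian"],
                           "cdi_english": cdi["english"],
                           "age_months": int(rng.integers(29, 40)),
                           "gender": rng.choice(["f", "m"])})

        for lang in config.languages:
            # items: fixed item->condition map (two balanced lists), order
            # randomized per participant as in the experiment software
            order = rng.permutation(np.arange(1, n_trials + 1))
            correct = rng.random(n_trials) >= config.pointing_error_rate
            trial_ids = [f"t{pos:02d}" for pos in range(1, n_trials + 1)]
            p_t = np.empty((n_trials, t_grid.size))
            for j, item in enumerate(order):
                trial_id = trial_ids[j]
                cond = "constraining" if item <= n_per_cond else "neutral"
                pointed[(pid, lang, trial_id)] = bool(correct[j])
                trial_rows.append({
                    "participant_id": pid,
                    "session_language": lang,
                    "trial_id": trial_id,
                    "item_id": f"item{item:02d}",
                    "condition": cond,
                    "target_side": "left" if item % 2 else "right",
                    "pointed_correct": bool(correct[j]),
                    "subject_figure": "boy" if (item // 2) % 2 else "girl",
                })
                if correct[j]:
                    onset_abs = (timing.verb_onset_ms + onsets[cond]
                                 + shifts[(pid, lang)])
                    curve = p_target_curve(t_grid, onset_abs, config)
                    p_t[j] = expit(logit(np.clip(curve, 1e-9, 1 - 1e-9))
                                   + prefs[(pid, lang)])
                else:
                    p_t[j] = 0.5

            p_tar = rest * p_t
            # cumulative cuts: fixpic | other | target | distractor
            c1 = np.broadcast_to(p_fix, p_t.shape)
            c2 = c1 + p_oth
            c3 = c2 + p_tar
            u = rng.random(p_t.shape)
            idx = ((u >= c1).astype(np.int8) + (u >= c2) + (u >= c3))
            if config.stickiness > 0.0:
                # first-order persistence: repeat the previous draw sometimes
                repeat = rng.random(p_t.shape) < config.stickiness
                for k in range(1, t_grid.size):
                    stick = repeat[:, k]
                    idx[stick, k] = idx[stick, k - 1]
            ev = rng.random(p_t.shape)
            ev_idx = ((ev >= config.p_event_other).astype(np.int8)
                      + (ev >= config.p_event_other + config.p_saccade))

            block = n_trials * t_grid.size
            col_pid.append(np.full(block, i, dtype=np.int16))
            col_lang.append(np.full(block, lang_levels.index(lang),
                                    dtype=np.int8))
            col_trial.append(np.repeat(
                np.arange(n_trials, dtype=np.int16), t_grid.size))
            col_aoi.append(idx.ravel().astype(np.int8))
            col_event.append(ev_idx.ravel().astype(np.int8))

    n_rows = sum(a.size for a in col_pid)

    def _cat(codes_list, levels, dtype):
        return pd.Categorical.from_codes(
            np.concatenate(codes_list).astype(dtype), categories=levels)

    samples = pd.DataFrame({
        "participant_id": _cat(col_pid, pid_levels, np.int16),
        "session_language": _cat(col_lang, lang_levels, np.int8),
        "trial_id": _cat(col_trial, trial_levels, np.int16),
        "t_ms": np.tile(t_grid, n_rows // t_grid.size),
        "event_type": _cat(col_event, event_levels, np.int8),
        "gaze_x": np.nan,
        "gaze_y": np.nan,
        "aoi": _cat(col_aoi, aoi_levels, np.int8),
    })
    samples = samples.sort_values(
        ["participant_id", "trial_id", "t_ms"], kind="stable"
    ).reset_index(drop=True)
    trials = pd.DataFrame(trial_rows)
    vocab = pd.DataFrame(vocab_rows)
    realized = 1.0 - np.mean([v for v in pointed.values()])
    truth = SyntheticTruth(
        config=config.to_dict(),
        onset_shift_ms=shifts,
        preference_logit=prefs,
        true_onset_after_verb_ms=onsets,
        pointed_correct=pointed,
        realized_pointing_error_rate=float(realized),
    )
    return samples, trials, vocab, truth


# ------------------------------------------------------------------ fixtures

FIXTURE_CONFIGS: dict[str, dict] = {
    # flat-chance data: no target preference anywhere, no heterogeneity
    "null": dict(seed=101, asymptote_p_target=0.5, baseline_p_target=0.5,
                 sigma_logit=0.0, sigma_onset_ms=0.0,
                 languages=("norwegian",)),
    # the default strong constraining effect, one language for compactness
    "strong_effect": dict(seed=202, languages=("norwegian",)),
    "single_participant": dict(seed=303, n_participants=1,
                               languages=("norwegian",)),
    "all_incorrect": dict(seed=404, n_participants=4,
                          pointing_error_rate=1.0, languages=("norwegian",)),
}


def make_fixture_suite(out_dir) -> dict[str, Path]:
    """Write the named unit-test fixture datasets with their manifests."""
    out_dir = Path(out_dir)
    written = {}
    for name, overrides in FIXTURE_CONFIGS.items():
        cfg = SyntheticConfig(**overrides)
        samples, trials, vocab, truth = generate_vwp_dataset(cfg)
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        vio.write_samples(samples, d / "samples.tsv")
        vio.write_trials(trials, d / "trials.tsv")
        vio.write_vocab(vocab, d / "vocab.tsv")
        truth.to_json(d / "truth.json")
        with open(d / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"name": name, "config": cfg.to_dict()}, fh, indent=1)
        written[name] = d
    return written
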