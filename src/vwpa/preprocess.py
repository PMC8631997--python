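"""Trial exclusion, AOI coding, time-binning and analysis-window construction.

The experiment presents a fixation picture (top middle) plus a target and a
distractor picture (lower left/right) while a sentence is played.  All timing
is trial-relative milliseconds: pictures appear at t=0, the audio starts
after a preview period, the verb and the noun of the carrier sentence start
at fixed offsets so that trials are comparable.

The critical predictive window runs from verb onset + saccade latency to
noun onset + the same latency: any target bias inside it can only be driven
by the verb.  A post-noun buffer extends the searched window so that a
divergence driven by hearing the noun itself (the neutral condition) can
still be located.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AOI_LABELS = ("target", "distractor", "fixation_picture", "other")
ANALYZED_EVENTS = ("fixation", "saccade")


@dataclass(frozen=True)
class TimingConfig:
    """Trial timing constants (ms, trial-relative) and sampling rate."""

    verb_onset_ms: int = 3500
    noun_onset_ms: int = 5300
    saccade_latency_ms: int = 300
    post_noun_buffer_ms: int = 1700
    bin_width_ms: int = 20
    sample_rate_hz: int = 250
    audio_onset_ms: int = 1000  # pictures preview before the audio starts

    def __post_init__(self) -> None:
        if self.verb_onset_ms >= self.noun_onset_ms:
            raise ValueError("verb_onset_ms must precede noun_onset_ms")
        if self.bin_width_ms <= 0:
            raise ValueError("bin_width_ms must be positive")
        span = self.noun_onset_ms - self.verb_onset_ms
        ext = span + self.post_noun_buffer_ms
        if span % self.bin_width_ms or ext % self.bin_width_ms:
            raise ValueError(
                "analysis window lengths must be divisible by bin_width_ms"
            )

    @property
    def prediction_span_ms(self) -> int:
        """Verb-to-noun span: the time available to predict the noun."""
        return self.noun_onset_ms - self.verb_onset_ms


@dataclass(frozen=True)
class AnalysisWindows:
    """Half-open [start, end) analysis windows, aligned to the bin grid."""

    critical: tuple[int, int]
    extended: tuple[int, int]
    n_bins: int

    def bin_starts(self, bin_width_ms: int) -> np.ndarray:
        return np.arange(self.extended[0], self.extended[1], bin_width_ms)


def make_windows(timing: TimingConfig) -> AnalysisWindows:
    """Build the critical and extended analysis windows from the timing.

    critical = [verb+latency, noun+latency); extended adds the post-noun
    buffer.  Defaults give [3800, 5600) and [3800, 7300) with 175 bins.
    """
    lo = timing.verb_onset_ms + timing.saccade_latency_ms
    hi = timing.noun_onset_ms + timing.saccade_latency_ms
    ext_hi = hi + timing.post_noun_buffer_ms
    for edge in (lo, hi, ext_hi):
        if edge % timing.bin_width_ms:
            raise ValueError(
                f"window edge {edge} ms is not aligned to the "
                f"{timing.bin_width_ms} ms bin grid"
            )
    n_bins = (ext_hi - lo) // timing.bin_width_ms
    return AnalysisWindows(critical=(lo, hi), extended=(lo, ext_hi), n_bins=n_bins)


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for the pointing-based trial exclusion."""

    n_total: int
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.n_excluded / self.n_total if self.n_total else 0.0


def apply_pointing_exclusion(
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop trials where the child pointed at the distractor.

    Pointing to the distractor after the sentence is read as incorrect
    sentence understanding, so those trials carry no interpretable
    prediction signal.  Idempotent.
    """
    if "pointed_correct" not in trials.columns:
        raise ValueError("trials table lacks a 'pointed_correct' column")
    keep = trials["pointed_correct"].astype(bool)
    report = ExclusionReport(n_total=len(trials), n_excluded=int((~keep).sum()))
    if report.n_retained == 0:
        raise ValueError(
            "all trials excluded by pointing accuracy; nothing to analyze"
        )
    logger.info(
        "pointing exclusion: %d/%d trials removed (%.1f%%)",
        report.n_excluded, report.n_total, report.rate_percent,
    )
    return trials.loc[keep].copy(), report


@dataclass(frozen=True)
class AoiLayout:
    """Screen geometry: fixation picture and the left/right picture slots.

    Rectangles are half-open pixel boxes (x0, y0, x1, y1) with y increasing
    downwards; they must not overlap, must lie on the screen, and the
    fixation picture sits above both picture slots.
    """

    screen_w: int = 1920
    screen_h: int = 1080
    fixation_rect: tuple[int, int, int, int] = (810, 60, 1110, 360)
    left_rect: tuple[int, int, int, int] = (160, 500, 760, 940)
    right_rect: tuple[int, int, int, int] = (1160, 500, 1760, 940)

    def __post_init__(self) -> None:
        rects = {
            "fixation_rect": self.fixation_rect,
            "left_rect": self.left_rect,
            "right_rect": self.right_rect,
        }
        for name, (x0, y0, x1, y1) in rects.items():
            if not (x0 < x1 and y0 < y1):
                raise ValueError(f"{name} is degenerate: {rects[name]}")
            if x0 < 0 or y0 < 0 or x1 > self.screen_w or y1 > self.screen_h:
                raise ValueError(f"{name} extends outside the screen")
        names = list(rects)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if _rects_overlap(rects[a], rects[b]):
                    raise ValueError(f"{a} and {b} overlap")
        if self.fixation_rect[3] > min(self.left_rect[1], self.right_rect[1]):
            raise ValueError(
                "fixation_rect must lie above the left/right picture slots"
            )

    def locate(self, x: float, y: float) -> str:
        """Label a pixel as fixation_picture / left / right / other."""
        for label, rect in (
            ("fixation_picture", self.fixation_rect),
            ("left", self.left_rect),
            ("right", self.right_rect),
        ):
            x0, y0, x1, y1 = rect
            if x0 <= x < x1 and y0 <= y < y1:
                return label
        return "other"

    def to_dict(self) -> dict:
        return {
            "screen_w": self.screen_w,
            "screen_h": self.screen_h,
            "fixation_rect": list(self.fixation_rect),
            "left_rect": list(self.left_rect),
            "right_rect": list(self.right_rect),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AoiLayout":
        return cls(
            screen_w=int(d["screen_w"]),
            screen_h=int(d["screen_h"]),
            fixation_rect=tuple(d["fixation_rect"]),
            left_rect=tuple(d["left_rect"]),
            right_rect=tuple(d["right_rect"]),
        )


def _rects_overlap(a, b) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def map_coordinates_to_aoi(
    x: float, y: float, layout: AoiLayout, target_side: str
) -> str:
    """Map one gaze point to an AOI label, resolving target vs distractor.

    ``target_side`` is the side ('left'/'right') on which the target picture
    was shown in that trial.  Points in no rectangle map to 'other'.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("gaze coordinates must be finite")
    side = layout.locate(x, y)
    if side in ("fixation_picture", "other"):
        return side
    return "target" if side == target_side else "distractor"


def map_coordinates_to_aoi_array(
    x: np.ndarray, y: np.ndarray, layout: AoiLayout, target_side: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`map_coordinates_to_aoi`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("gaze coordinates must be finite")
    out = np.full(x.shape, "other", dtype=object)
    fx0, fy0, fx1, fy1 = layout.fixation_rect
    in_fix = (x >= fx0) & (x < fx1) & (y >= fy0) & (y < fy1)
    out[in_fix] = "fixation_picture"
    for side, rect in (("left", layout.left_rect), ("right", layout.right_rect)):
        x0, y0, x1, y1 = rect
        inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
        is_target = np.asarray(target_side, dtype=object) == side
        out[inside & is_target] = "target"
        out[inside & ~is_target] = "distractor"
    n_off = int(((x < 0) | (x >= layout.screen_w) | (y < 0) | (y >= layout.screen_h)).sum())
    if n_off:
        logger.warning("%d gaze samples fall off-screen; coded as 'other'", n_off)
    return out


def bin_fixations(
    samples: pd.DataFrame, trials: pd.DataFrame, timing: TimingConfig
) -> pd.DataFrame:
    """Count analyzed samples per (participant, language, condition, item, bin).

    Only fixation and saccade samples are counted (young children saccade
    within areas of sustained attention, so saccades carry signal too);
    blink/track-loss samples are dropped with a logged count.  Bins are
    half-open ``[start, start + bin_width)`` labelled by their left edge, so
    each sample lands in exactly one bin and one AOI counter.

    Returns the BinTable with columns n_target, n_distractor, n_fixpic,
    n_other.
    """
    required = {"participant_id", "session_language", "trial_id", "t_ms",
                "event_type", "aoi"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns: {sorted(missing)}")

    keys = ["participant_id", "session_language", "trial_id"]
    trial_index = pd.MultiIndex.from_frame(trials[keys])
    sample_keys = pd.MultiIndex.from_frame(samples[keys])
    trial_row = trial_index.get_indexer(sample_keys)  # -1 = unknown/excluded
    known = trial_row >= 0
    n_dropped_trials = int((~known).sum())
    if n_dropped_trials:
        logger.info(
            "binning: %d samples referenced excluded/unknown trials and were dropped",
            n_dropped_trials,
        )
    analyzed_mask = known & samples["event_type"].isin(ANALYZED_EVENTS).to_numpy()
    n_dropped_events = int(known.sum()) - int(analyzed_mask.sum())
    if n_dropped_events:
        logger.info(
            "binning: %d samples with event_type outside %s dropped",
            n_dropped_events, ANALYZED_EVENTS,
        )

    # integer-coded counting: (trial row, time bin, aoi) -> bincount
    trial_row = trial_row[analyzed_mask]
    t = samples.loc[analyzed_mask, "t_ms"].to_numpy(np.int64)
    bin_idx = t // timing.bin_width_ms
    n_bins_total = int(bin_idx.max()) + 1 if bin_idx.size else 0
    aoi_code = pd.Categorical(
        samples.loc[analyzed_mask, "aoi"], categories=AOI_LABELS
    ).codes.astype(np.int64)
    if (aoi_code < 0).any():
        raise ValueError("samples hold AOI labels outside the known set")
    n_trials_rows = len(trials)
    flat = (trial_row * n_bins_total + bin_idx) * 4 + aoi_code
    counts = np.bincount(flat, minlength=n_trials_rows * n_bins_total * 4)
    counts = counts.reshape(n_trials_rows, n_bins_total, 4)
    occupied = counts.sum(axis=2) > 0
    trial_of_cell, bin_of_cell = np.nonzero(occupied)
    cells = counts[trial_of_cell, bin_of_cell]
    out = pd.DataFrame({
        "participant_id": trials["participant_id"].to_numpy()[trial_of_cell],
        "session_language": trials["session_language"].to_numpy()[trial_of_cell],
        "condition": trials["condition"].to_numpy()[trial_of_cell],
        "item_id": trials["item_id"].to_numpy()[trial_of_cell],
        "bin_start_ms": bin_of_cell * timing.bin_width_ms,
        "n_target": cells[:, 0],
        "n_distractor": cells[:, 1],
        "n_fixpic": cells[:, 2],
        "n_other": cells[:, 3],
    })
    cap = math.ceil(timing.bin_width_ms * timing.sample_rate_hz / 1000)
    # per-trial cap; with one item per trial the item is the trial here
    totals = out[["n_target", "n_distractor", "n_fixpic", "n_other"]].sum(axis=1)
    if (totals > cap).any():
        logger.warning(
            "some bins hold more samples than bin_width*rate allows "
            "(max %d > cap %d); check for duplicated samples",
            int(totals.max()), cap,
        )
    return out.sort_values(
        ["participant_id", "session_language", "condition", "item_id",
         "bin_start_ms"]
    ).reset_index(drop=True)
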