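"""Fixation-percentage curves with 95% confidence intervals per 20-ms bin.

The unit of variation is the participant: for each (language, condition,
bin, AOI) the per-participant fixation percentage is computed first (pooling
that participant's retained trials), then the mean and a normal-
approximation 95% CI across participants.  Participants with no retained
samples in a bin are omitted from that bin; bins with fewer than two
contributing participants report the mean with empty CI fields.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AnalysisWindows, TimingConfig

logger = logging.getLogger(__name__)

_COUNT_TO_AOI = {
    "n_target": "target",
    "n_distractor": "distractor",
    "n_fixpic": "fixation_picture",
    "n_other": "other",
}
Z95 = 1.959963984540054  # two-sided 95% normal quantile


def compute_curves(bins: pd.DataFrame) -> pd.DataFrame:
    """Mean fixation percentage and 95% CI per (language, condition, AOI, bin)."""
    if bins.empty:
        raise ValueError("empty BinTable")
    count_cols = list(_COUNT_TO_AOI)
    per_part = (
        bins.groupby(["session_language", "condition", "participant_id",
                      "bin_start_ms"], observed=True)[count_cols]
        .sum()
    )
    totals = per_part.sum(axis=1)
    per_part = per_part.loc[totals > 0]
    totals = totals.loc[totals > 0]
    pct = per_part.div(totals, axis=0) * 100.0
    pct = pct.rename(columns=_COUNT_TO_AOI)
    long = pct.reset_index().melt(
        id_vars=["session_language", "condition", "participant_id",
                 "bin_start_ms"],
        var_name="aoi", value_name="percent",
    )
    g = long.groupby(["session_language", "condition", "aoi", "bin_start_ms"],
                     observed=True)["percent"]
    out = g.agg(mean_percent="mean", _sd="std", n_participants="count")
    se = out["_sd"] / np.sqrt(out["n_participants"])
    out["ci_low"] = (out["mean_percent"] - Z95 * se).clip(lower=0.0)
    out["ci_high"] = (out["mean_percent"] + Z95 * se).clip(upper=100.0)
    single = out["n_participants"] < 2
    out.loc[single, ["ci_low", "ci_high"]] = np.nan
    out = out.drop(columns="_sd").reset_index()
    return out[["session_language", "condition", "aoi", "bin_start_ms",
                "mean_percent", "ci_low", "ci_high", "n_participants"]]


_AOI_STYLE = {
    "target": dict(color="#1a7f37"),
    "distractor": dict(color="#c0392b"),
    "fixation_picture": dict(color="#2d6ca2"),
    "other": dict(color="#7f8c8d"),
}


def plot_curves(
    curves: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    timing: TimingConfig | None = None,
    out_dir=".",
    fmt: str = "png",
    divergence: dict | None = None,
) -> list[Path]:
    """Write one fixation-curve figure per language (panels per condition).

    Vertical markers show context (audio) start, verb onset and noun onset;
    if ``divergence`` maps (language, condition) to a divergence point in
    ms after verb onset, a triangle marks it on the target curve.
    Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    timing = timing or TimingConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for lang, lang_curves in curves.groupby("session_language", observed=True):
        conditions = sorted(lang_curves["condition"].unique(),
                            key=lambda c: (c != "constraining", c))
        fig, axes = plt.subplots(
            1, len(conditions), figsize=(6.0 * len(conditions), 4.0),
            sharey=True, squeeze=False,
        )
        for ax, cond in zip(axes[0], conditions):
            sub = lang_curves[lang_curves["condition"] == cond]
            for aoi, style in _AOI_STYLE.items():
                s = sub[sub["aoi"] == aoi].sort_values("bin_start_ms")
                if s.empty:
                    continue
                ax.plot(s["bin_start_ms"], s["mean_percent"],
                        label=aoi.replace("_", " "), **style)
                ax.fill_between(s["bin_start_ms"], s["ci_low"], s["ci_high"],
                                alpha=0.2, linewidth=0, **style)
            for t, label in ((timing.audio_onset_ms, "context"),
                             (timing.verb_onset_ms, "verb"),
                             (timing.noun_onset_ms, "noun")):
                ax.axvline(t, color="k", linestyle=":", linewidth=0.8)
                ax.annotate(label, (t, 98), ha="center", fontsize=8)
            if divergence is not None:
                dp = divergence.get((lang, cond))
                if dp is not None:
                    ax.plot([timing.verb_onset_ms + dp], [50], marker="v",
                            color="k", markersize=9, zorder=5)
            ax.set_title(f"{lang} - {cond}")
            ax.set_xlabel("time from trial onset (ms)")
            ax.set_ylim(0, 100)
        axes[0][0].set_ylabel("fixation percentage")
        axes[0][-1].legend(loc="upper left", fontsize=8)
        fig.tight_layout()
        path = out_dir / f"curves_{lang}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
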