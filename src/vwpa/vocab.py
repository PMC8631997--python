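"""Predictive-ability scores and their correlations with vocabulary.

Predictive ability is the difference in target fixations between the
constraining and the neutral condition inside the critical predictive
window, computed per participant and session language.  Because the number
of retained trials differs across children after the pointing exclusion,
the default score normalizes to a mean target-sample count per retained
trial; a raw count and a proportion mode are also provided.

Expressive vocabulary is the CDI word count per language; total vocabulary
is the plain sum over the two languages.  Associations are measured with
tie-corrected Spearman rank correlations (p from the t-approximation with
n - 2 df, exact permutation p available for very small n).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import AnalysisWindows

logger = logging.getLogger(__name__)

SCORE_MODES = ("per_trial_mean", "raw_count", "proportion")


def predictive_ability(
    bins: pd.DataFrame,
    windows: AnalysisWindows,
    mode: str = "per_trial_mean",
    trials: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per participant x language predictive-ability scores.

    Modes
    -----
    per_trial_mean (default)
        mean target-sample count per retained trial in the critical window,
        constraining minus neutral.
    raw_count
        total target-sample count difference (the literal reading; it
        confounds data quantity with prediction when retained-trial counts
        differ).
    proportion
        target / (target + distractor) share difference.

    ``trials`` (the exclusion-filtered TrialTable) supplies retained-trial
    counts for per_trial_mean; when omitted, trials are counted as distinct
    items present in the BinTable.  Participants lacking retained trials in
    either condition get an undefined (NaN) score and are excluded from
    correlations downstream.
    """
    if mode not in SCORE_MODES:
        raise ValueError(f"unknown score mode {mode!r}")
    lo, hi = windows.critical
    win = bins[(bins["bin_start_ms"] >= lo) & (bins["bin_start_ms"] < hi)]
    keys = ["participant_id", "session_language", "condition"]
    agg = win.groupby(keys, observed=True)[["n_target", "n_distractor"]].sum()

    if trials is not None:
        n_trials = trials.groupby(keys, observed=True)["trial_id"].nunique()
    else:
        n_trials = bins.groupby(keys, observed=True)["item_id"].nunique()
    agg = agg.join(n_trials.rename("n_trials"), how="outer").fillna(
        {"n_target": 0, "n_distractor": 0})
    agg = agg[agg["n_trials"].fillna(0) > 0]

    if mode == "per_trial_mean":
        value = agg["n_target"] / agg["n_trials"]
    elif mode == "raw_count":
        value = agg["n_target"].astype(float)
    else:
        denom = agg["n_target"] + agg["n_distractor"]
        value = agg["n_target"] / denom.where(denom > 0)

    wide = value.unstack("condition")
    for cond in ("constraining", "neutral"):
        if cond not in wide.columns:
            wide[cond] = np.nan
    score = (wide["constraining"] - wide["neutral"]).rename(
        "predictive_ability")
    undefined = score.isna()
    if undefined.any():
        logger.info(
            "predictive ability undefined for %d participant-language cells "
            "(missing retained trials in one condition)", int(undefined.sum()),
        )
    return score.reset_index()


def total_vocabulary(vocab: pd.DataFrame) -> pd.DataFrame:
    """Add cdi_total = cdi_norwegian + cdi_english; incomplete rows get NaN."""
    out = vocab.copy()
    both = out[["cdi_norwegian", "cdi_english"]].notna().all(axis=1)
    out["cdi_total"] = np.where(
        both, out["cdi_norwegian"] + out["cdi_english"], np.nan)
    n_flagged = int((~both).sum())
    if n_flagged:
        logger.warning(
            "%d children lack a CDI score in one language; excluded from "
            "total-vocabulary correlations", n_flagged,
        )
    return out


@dataclass
class CorrelationResult:
    """A Spearman correlation between two participant-level measures."""

    pair: str
    r: float | None
    p: float | None
    n: int

    def as_dict(self) -> dict:
        return {"pair": self.pair, "r": self.r, "p": self.p, "n": self.n}


def spearman_correlation(
    x, y, pair: str = "", exact_permutation: bool = False
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation.

    p comes from the t-approximation with n - 2 df; with
    ``exact_permutation`` (only for n <= 10) the two-sided p is computed by
    full enumeration of rank permutations.  Zero variance in either input
    yields r = None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return CorrelationResult(pair, None, None, n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in %s; correlation undefined", pair or
                       "correlation input")
        return CorrelationResult(pair, None, None, n)
    rho, p = stats.spearmanr(x, y)
    if exact_permutation:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        p = count / total
    return CorrelationResult(pair, float(rho), float(p), n)


def correlation_report(
    scores: pd.DataFrame,
    vocab: pd.DataFrame,
    out_dir=None,
    fmt: str = "png",
) -> pd.DataFrame:
    """The four score-vocabulary correlations (plus optional scatter plots).

    Rows: predictive ability per language against the same-language CDI and
    against the total CDI.  Fewer than 3 complete cases yields r = None for
    that row.  When ``out_dir`` is given, one scatter figure per vocabulary
    measure is written.
    """
    vocab = total_vocabulary(vocab)
    merged = scores.merge(vocab, on="participant_id", how="left")
    results = []
    pairs = []
    for lang in ("norwegian", "english"):
        sub = merged[merged["session_language"] == lang]
        for vocab_col, label in ((f"cdi_{lang}", f"cdi_{lang}"),
                                 ("cdi_total", "cdi_total")):
            pair = f"predictive_{lang}_vs_{label}"
            res = spearman_correlation(
                sub["predictive_ability"], sub[vocab_col], pair=pair)
            results.append(res)
            pairs.append((lang, vocab_col, pair, sub))
    table = pd.DataFrame([r.as_dict() for r in results])

    if out_dir is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for figure_name, cols in (
            ("correlations_same_language", ["cdi_norwegian", "cdi_english"]),
            ("correlations_total", ["cdi_total", "cdi_total"]),
        ):
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            for ax, lang, col in zip(axes, ("norwegian", "english"),
                                     cols):
                sub = merged[merged["session_language"] == lang]
                ax.scatter(sub[col], sub["predictive_ability"], s=25,
                           color="#2d6ca2")
                row = table[table["pair"] == f"predictive_{lang}_vs_{col}"]
                r = row["r"].iloc[0] if len(row) else None
                rtxt = "undefined" if r is None or pd.isna(r) else f"{r:.2f}"
                ax.set_title(f"{lang}: r = {rtxt}")
                ax.set_xlabel(col)
                ax.set_ylabel("predictive ability")
            fig.tight_layout()
            fig.savefig(out_dir / f"{figure_name}.{fmt}", dpi=120)
            plt.close(fig)
    return table
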