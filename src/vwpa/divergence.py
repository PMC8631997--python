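"""Divergence-point estimation: when do target fixations leave chance?

For one (session language, condition) cell, every 20-ms bin of the extended
analysis window is tested with an intercept-only logistic mixed model on the
per-cluster target/distractor counts.  The per-bin p-values are adjusted
for multiple comparisons jointly across all bins of the window (FDR by
default), and the divergence point is the earliest bin whose adjusted
p-value falls below alpha with a positive intercept (more target than
distractor looks).  The divergence is reported in ms after verb onset.

The module is organized statsmodels-style: build a
:class:`DivergencePointModel` from a BinTable, call :meth:`fit`, inspect
the returned :class:`DivergencePointResults` (per-bin fits, estimate,
``summary()``).  The functional wrappers :func:`estimate_divergence` and
:func:`summarize_results` cover the same ground for pipeline use.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .glmm import (AnalysisConfig, BinFit, adjust_pvalues, fit_bin_glm,
                   fit_bin_glmm)
from .preprocess import AnalysisWindows, TimingConfig, make_windows

logger = logging.getLogger(__name__)


class DivergencePointModel:
    """Per-bin mixed-model divergence analysis for one language x condition.

    Parameters
    ----------
    bins
        BinTable (output of :func:`vwpa.preprocess.bin_fixations`), already
        restricted to exclusion-filtered trials.  If it spans several
        languages/conditions, pass ``session_language``/``condition`` to
        subset.
    timing, windows, config
        Timing constants, analysis windows (derived from timing when
        omitted) and test configuration.
    """

    def __init__(
        self,
        bins: pd.DataFrame,
        timing: TimingConfig | None = None,
        windows: AnalysisWindows | None = None,
        config: AnalysisConfig | None = None,
        session_language: str | None = None,
        condition: str | None = None,
    ) -> None:
        self.timing = timing or TimingConfig()
        self.windows = windows or make_windows(self.timing)
        self.config = config or AnalysisConfig()
        if session_language is not None:
            bins = bins[bins["session_language"] == session_language]
        if condition is not None:
            bins = bins[bins["condition"] == condition]
        for col in ("session_language", "condition"):
            if bins[col].nunique() > 1:
                raise ValueError(
                    f"BinTable spans several values of {col}; subset first "
                    f"({sorted(bins[col].unique())})"
                )
        if bins.empty:
            raise ValueError("empty BinTable")
        self.session_language = bins["session_language"].iloc[0]
        self.condition = bins["condition"].iloc[0]
        if bins["participant_id"].nunique() < 2:
            raise ValueError(
                "divergence analysis needs at least 2 participants")
        self.bins = bins

    def fit(self) -> "DivergencePointResults":
        cfg = self.config
        lo, hi = self.windows.extended
        width = self.timing.bin_width_ms
        bin_starts = np.arange(lo, hi, width)
        groups = {
            b: g for b, g in self.bins.groupby("bin_start_ms", observed=True)
        }
        fits: list[BinFit] = []
        for b in bin_starts:
            g = groups.get(b)
            if g is None or (g["n_target"].sum() + g["n_distractor"].sum()) == 0:
                fits.append(BinFit(float(b), np.nan, np.nan, np.nan, 1.0,
                                   converged=False, method="no_data"))
                continue
            fits.append(
                fit_bin_glmm(
                    g["n_target"].to_numpy(), g["n_distractor"].to_numpy(),
                    g["participant_id"].to_numpy(),
                    items=g["item_id"].to_numpy(),
                    config=cfg, bin_start_ms=float(b),
                )
            )
        p_adj = adjust_pvalues([f.p for f in fits], cfg.correction)
        for f, pa in zip(fits, p_adj):
            f.p_adj = float(pa)

        sig = np.array([
            f.p_adj < cfg.alpha
            and (f.beta0 > 0 or not cfg.require_positive_direction)
            and np.isfinite(f.beta0)
            for f in fits
        ])
        div_idx = _first_run(sig, cfg.min_run)
        divergence = None
        if div_idx is not None:
            divergence = float(bin_starts[div_idx] - self.timing.verb_onset_ms)
        return DivergencePointResults(model=self, bin_fits=fits,
                                      _div_idx=div_idx,
                                      divergence_ms_after_verb=divergence)


def _first_run(sig: np.ndarray, min_run: int) -> int | None:
    """Index of the first position opening >= min_run consecutive True."""
    if min_run == 1:
        hits = np.flatnonzero(sig)
        return int(hits[0]) if hits.size else None
    for i in range(len(sig) - min_run + 1):
        if sig[i:i + min_run].all():
            return i
    return None


@dataclass
class DivergencePointResults:
    """Fitted divergence analysis: estimate, per-bin fits, diagnostics."""

    model: DivergencePointModel
    bin_fits: list[BinFit]
    divergence_ms_after_verb: float | None
    _div_idx: int | None = None

    @property
    def session_language(self) -> str:
        return self.model.session_language

    @property
    def condition(self) -> str:
        return self.model.condition

    @property
    def in_critical_window(self) -> bool:
        """True when the divergence precedes noun onset + saccade latency."""
        if self.divergence_ms_after_verb is None:
            return False
        t = self.model.timing
        limit = t.noun_onset_ms + t.saccade_latency_ms - t.verb_onset_ms
        return self.divergence_ms_after_verb < limit

    @property
    def z_at_divergence(self) -> float | None:
        if self._div_idx is None:
            return None
        return self.bin_fits[self._div_idx].z

    @property
    def p_adj_at_divergence(self) -> float | None:
        if self._div_idx is None:
            return None
        return self.bin_fits[self._div_idx].p_adj

    def bin_table(self) -> pd.DataFrame:
        """Per-bin fits as a DataFrame (one row per bin of the window)."""
        df = pd.DataFrame([asdict(f) for f in self.bin_fits])
        df.insert(0, "condition", self.condition)
        df.insert(0, "session_language", self.session_language)
        return df

    def fit_provenance(self) -> dict:
        """How many bins used which fitting route (audit of fallbacks)."""
        methods = pd.Series([f.method for f in self.bin_fits])
        return methods.value_counts().to_dict()

    def summary(self) -> str:
        lines = [
            "Divergence point analysis "
            f"({self.session_language}, {self.condition})",
            f"  bins tested: {len(self.bin_fits)} "
            f"[{self.model.windows.extended[0]}, "
            f"{self.model.windows.extended[1]}) ms, "
            f"correction={self.model.config.correction}, "
            f"alpha={self.model.config.alpha}",
        ]
        if self.divergence_ms_after_verb is None:
            lines.append("  divergence point: none (no significant bin)")
        else:
            where = ("inside" if self.in_critical_window else "outside")
            lines.append(
                f"  divergence point: {self.divergence_ms_after_verb:.0f} ms "
                f"after verb onset ({where} the critical window), "
                f"z = {self.z_at_divergence:.2f}, "
                f"adjusted p = {self.p_adj_at_divergence:.4f}"
            )
        prov = ", ".join(f"{k}: {v}" for k, v in
                         sorted(self.fit_provenance().items()))
        lines.append(f"  fit provenance: {prov}")
        return "\n".join(lines)


def estimate_divergence(
    bins: pd.DataFrame,
    windows: AnalysisWindows | None = None,
    timing: TimingConfig | None = None,
    config: AnalysisConfig | None = None,
    session_language: str | None = None,
    condition: str | None = None,
) -> DivergencePointResults:
    """Fit a :class:`DivergencePointModel` in one call."""
    model = DivergencePointModel(
        bins, timing=timing, windows=windows, config=config,
        session_language=session_language, condition=condition,
    )
    return model.fit()


def summarize_results(results) -> pd.DataFrame:
    """Tabulate divergence estimates per condition with language differences.

    Accepts an iterable of :class:`DivergencePointResults` (one per
    language x condition).  Emits one row per condition with the estimate,
    z and adjusted p per language, plus the english - norwegian difference
    in ms; missing cells yield NA entries.
    """
    cells: dict[tuple[str, str], DivergencePointResults] = {}
    for r in results:
        key = (r.condition, r.session_language)
        if key in cells:
            raise ValueError(f"duplicate result for {key}")
        cells[key] = r
    return _summary_frame(cells)


def summary_from_estimates(estimates: dict) -> pd.DataFrame:
    """Summary table from bare divergence estimates.

    ``estimates`` maps (condition, language) to a divergence point in ms
    after verb onset (or None).  Useful to tabulate language differences
    for externally reported estimates; z/p columns come out as NA.
    """
    cells = {}
    for (cond, lang), value in estimates.items():
        cells[(cond, lang)] = _BareEstimate(value)
    return _summary_frame(cells)


class _BareEstimate:
    def __init__(self, divergence_ms):
        self.divergence_ms_after_verb = divergence_ms
        self.z_at_divergence = None
        self.p_adj_at_divergence = None
        self.in_critical_window = pd.NA


def _summary_frame(cells) -> pd.DataFrame:
    rows = []
    conditions = sorted({c for c, _ in cells},
                        key=lambda c: (c != "constraining", c))
    for cond in conditions:
        row: dict = {"condition": cond}
        for lang in ("norwegian", "english"):
            r = cells.get((cond, lang))
            prefix = lang
            row[f"{prefix}_divergence_ms"] = (
                np.nan if r is None or r.divergence_ms_after_verb is None
                else r.divergence_ms_after_verb)
            row[f"{prefix}_z"] = (np.nan if r is None or r.z_at_divergence is None
                                  else r.z_at_divergence)
            row[f"{prefix}_p_adj"] = (
                np.nan if r is None or r.p_adj_at_divergence is None
                else r.p_adj_at_divergence)
            row[f"{prefix}_in_critical_window"] = (
                r.in_critical_window if r is not None else pd.NA)
        row["difference_ms"] = (
            row["english_divergence_ms"] - row["norwegian_divergence_ms"])
        rows.append(row)
    return pd.DataFrame(rows)
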