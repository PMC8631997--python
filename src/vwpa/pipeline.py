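"""End-to-end orchestration: exclusion -> binning -> curves -> divergence ->
scores -> correlations, with a JSON run manifest.

A single YAML/dict config drives the run.  Either point it at sample/trial/
vocab tables::

    inputs:
      samples: path/to/samples.tsv
      trials: path/to/trials.tsv
      vocab: path/to/vocab.tsv

or ask for a synthetic dataset::

    synthetic:
      seed: 7
      # any SyntheticConfig field

Optional sections: ``timing`` (TimingConfig fields), ``analysis``
(AnalysisConfig fields), ``score_mode``, ``plots`` (bool).  The manifest
written next to the outputs echoes the full effective config, the exclusion
report, per-analysis fit provenance, and the output file list, and is
sufficient to re-run the pipeline identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as vio
from .curves import compute_curves, plot_curves
from .divergence import estimate_divergence, summarize_results
from .glmm import AnalysisConfig
from .preprocess import (TimingConfig, apply_pointing_exclusion,
                         bin_fixations, make_windows)
from .simulate import SyntheticConfig, generate_vwp_dataset
from .vocab import correlation_report, predictive_ability

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def _build_configs(cfg: dict):
    timing = TimingConfig(**cfg.get("timing", {}))
    analysis = AnalysisConfig(**cfg.get("analysis", {}))
    score_mode = cfg.get("score_mode", "per_trial_mean")
    return timing, analysis, score_mode


def run_pipeline(config, out_dir, no_plots: bool | None = None) -> dict:
    """Run the full analysis; returns the manifest (also written as JSON)."""
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timing, analysis, score_mode = _build_configs(cfg)
    windows = make_windows(timing)
    if no_plots is None:
        no_plots = not cfg.get("plots", True)
    outputs: list[str] = []
    manifest: dict = {
        "vwpa_version": __version__,
        "config": {
            "timing": dataclasses.asdict(timing),
            "analysis": dataclasses.asdict(analysis),
            "score_mode": score_mode,
            "plots": not no_plots,
        },
        "windows": {"critical": list(windows.critical),
                    "extended": list(windows.extended),
                    "n_bins": windows.n_bins},
    }

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # ---- inputs
    if "synthetic" in cfg:
        syn_kwargs = dict(cfg["synthetic"])
        if "timing" not in syn_kwargs:
            syn_kwargs["timing"] = timing
        syn = SyntheticConfig(**syn_kwargs)
        samples, trials, vocab, truth = _stage(
            "simulate", generate_vwp_dataset, syn)
        manifest["config"]["synthetic"] = syn.to_dict()
        outputs.append(str(truth.to_json(out_dir / "truth.json")))
    elif "inputs" in cfg:
        paths = cfg["inputs"]
        trials = _stage("read_trials", vio.read_trial_metadata, paths["trials"])
        layout = (vio.read_layout(paths["layout"])
                  if "layout" in paths else None)
        samples = _stage("read_samples", vio.read_gaze_samples,
                         paths["samples"], layout=layout, trials=trials)
        vocab = (_stage("read_vocab", vio.read_cdi_scores, paths["vocab"])
                 if "vocab" in paths else None)
        manifest["config"]["inputs"] = {k: str(v) for k, v in paths.items()}
    else:
        raise PipelineError("config needs an 'inputs' or 'synthetic' section")

    # ---- exclusion and binning
    retained, report = _stage("exclusion", apply_pointing_exclusion, trials)
    manifest["exclusion"] = {"n_total": report.n_total,
                             "n_excluded": report.n_excluded,
                             "rate_percent": report.rate_percent}
    logger.info("exclusion: %d -> %d trials", report.n_total, report.n_retained)
    bins = _stage("binning", bin_fixations, samples, retained, timing)
    outputs.append(str(vio.write_table(bins, out_dir / "bins.tsv")))
    logger.info("binning: %d samples -> %d bin rows", len(samples), len(bins))

    # ---- curves
    curve_table = _stage("curves", compute_curves, bins)
    outputs.append(str(vio.write_table(curve_table, out_dir / "curves.tsv")))

    # ---- divergence per language x condition
    results = []
    provenance = {}
    for (lang, cond), _ in bins.groupby(
            ["session_language", "condition"], observed=True):
        res = _stage(f"divergence[{lang},{cond}]", estimate_divergence,
                     bins, windows=windows, timing=timing, config=analysis,
                     session_language=lang, condition=cond)
        results.append(res)
        provenance[f"{lang}/{cond}"] = res.fit_provenance()
        outputs.append(str(vio.write_table(
            res.bin_table(), out_dir / f"bin_fits_{lang}_{cond}.tsv")))
    summary = summarize_results(results)
    outputs.append(str(vio.write_table(summary, out_dir / "divergence_summary.tsv")))
    manifest["fit_provenance"] = provenance
    manifest["divergence"] = {
        f"{r.session_language}/{r.condition}": r.divergence_ms_after_verb
        for r in results
    }

    if not no_plots:
        div_points = {(r.session_language, r.condition):
                      r.divergence_ms_after_verb for r in results}
        figs = _stage("plot_curves", plot_curves, curve_table, windows,
                      timing, out_dir=out_dir, divergence=div_points)
        outputs.extend(str(p) for p in figs)

    # ---- scores and correlations
    scores = _stage("scores", predictive_ability, bins, windows,
                    mode=score_mode, trials=retained)
    outputs.append(str(vio.write_table(scores, out_dir / "scores.tsv")))
    if vocab is not None and len(vocab):
        corr = _stage("correlations", correlation_report, scores, vocab,
                      out_dir=None if no_plots else out_dir)
        outputs.append(str(vio.write_table(corr, out_dir / "correlations.tsv")))

    manifest["outputs"] = sorted(outputs)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
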