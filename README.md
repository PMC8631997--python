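# vwpa — divergence-point analysis for visual-world-paradigm eye tracking

`vwpa` turns raw gaze samples and trial metadata from a visual-world-paradigm
(VWP) experiment into estimates of *when* listeners start fixating a target
picture above chance — the divergence point — and into participant-level
predictive-ability scores and their correlations with expressive vocabulary.
It is aimed at developmental and psycholinguistic researchers running
looking-while-listening designs in which a spoken verb may or may not
semantically constrain an upcoming noun (e.g. *The boy **eats/takes** the
green apple* with an edible target and an inedible distractor on screen).

## What it computes

Trials are time-locked so the verb starts at 3,500 ms and the noun at
5,300 ms. Adding a 300 ms saccade-launch latency defines the **critical
predictive window** [3,800, 5,600): target bias inside it can only come from
the verb. A 1,700 ms post-noun buffer extends the searched window to
7,300 ms (175 bins of 20 ms).

Per 20-ms bin *t*, the target/distractor sample counts are modelled with an
intercept-only logistic mixed model

> y_ij ~ Binomial(n_ij, p_ij),  logit p_ij = β₀ + u_i (+ v_j),
> u_i ~ N(0, σ²_participant), v_j ~ N(0, σ²_item)

fitted by Laplace approximation, with a Wald test of H₀: β₀ = 0 (chance).
The per-bin p-values are Benjamini–Hochberg corrected across all bins of the
extended window; the **divergence point** is the earliest bin with adjusted
p < α and β₀ > 0, reported in ms after verb onset.

Around this core the package provides: pointing-based trial exclusion,
AOI coding from gaze coordinates, fixation-percentage curves with 95% CIs
per bin, predictive-ability scores (constraining − neutral target fixations
in the critical window), tie-corrected Spearman correlations with per-
language and total CDI vocabulary, and a synthetic-data generator with
known ground truth (onsets, random effects, pointing errors) so every stage
is testable without any participant data.

## Worked example

```python
from vwpa import (SyntheticConfig, generate_vwp_dataset,
                  apply_pointing_exclusion, bin_fixations, AnalysisConfig)
from vwpa.divergence import DivergencePointModel

cfg = SyntheticConfig(seed=7, languages=("norwegian",))
samples, trials, vocab, truth = generate_vwp_dataset(cfg)

retained, report = apply_pointing_exclusion(trials)
print(f"retained {report.n_retained}/{report.n_total} trials "
      f"({report.rate_percent:.1f}% excluded)")

bins = bin_fixations(samples, retained, cfg.timing)
model = DivergencePointModel(bins, timing=cfg.timing,
                             condition="constraining",
                             config=AnalysisConfig(random_effects="participant"))
print(model.fit().summary())
```

prints

```
retained 221/238 trials (7.1% excluded)
Divergence point analysis (norwegian, constraining)
  bins tested: 175 [3800, 7300) ms, correction=fdr, alpha=0.05
  divergence point: 1020 ms after verb onset (inside the critical window), z = 2.82, adjusted p = 0.0062
  fit provenance: glmm_participant: 141, glmm_participant_boundary: 34
```

The generator placed the true constraining onset at 1,000 ms after the
verb; the estimator finds the divergence one bin later, inside the critical
window, with the mixed model used in 141 bins and the zero-variance (pooled
GLM) boundary in 34. The `truth` object carries the per-participant onset
shifts and pointing outcomes for recovery checks.

The same analysis is available from the shell:

```sh
vwpa simulate --seed 7 --out data/
vwpa analyze --config config.yaml --out results/   # full pipeline + figures
vwpa divergence --data data/ --out results/        # stats only
```

with a YAML config such as

```yaml
synthetic: {seed: 7}          # or inputs: {samples: ..., trials: ..., vocab: ...}
analysis: {alpha: 0.05, correction: fdr, random_effects: participant+item}
score_mode: per_trial_mean
plots: true
```

Every run writes a `manifest.json` (effective config, exclusion report,
per-bin fit provenance, output list) sufficient to re-run it identically.

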