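# Methods

This note documents the models, the numerical choices, the synthetic-data
generator, and the known limitations of the estimators.

## Design and timing

The analysis assumes a two-picture visual-world design with a fixation
picture: each trial shows the pictures for a preview second, then plays a
context sentence followed by a carrier sentence whose verb starts at
3,500 ms and whose noun starts at 5,300 ms into the trial (both enforced by
stimulus editing, so trials are alignable without warping). All defaults:

| parameter | default | meaning |
|---|---|---|
| `verb_onset_ms` | 3500 | verb onset, trial-relative |
| `noun_onset_ms` | 5300 | noun onset; prediction span = 1,800 ms |
| `saccade_latency_ms` | 300 | time to program/launch a saccade in toddlers |
| `post_noun_buffer_ms` | 1700 | extends the searched window past the noun |
| `bin_width_ms` | 20 | analysis bin; half-open [start, start+20) |
| `sample_rate_hz` | 250 | eye-tracker sampling rate |

Critical window [3,800, 5,600), extended window [3,800, 7,300), 175 bins.
Bins are labelled by their left edge; divergence points are reported as
`bin_start − verb_onset` (so they land on the 20-ms grid).

Trials in which the child pointed at the distractor after the sentence are
excluded before any statistic (incorrect sentence understanding). Both
fixation and saccade samples are analyzed — young children saccade within
regions of sustained attention — while blink/track-loss samples are
dropped with a logged count; there is no trial-level data-quality
exclusion. Samples on the fixation picture or outside every region are kept
in the bin table for curve plotting but excluded from the binomial
denominator of the statistics, which compares target against distractor
looks only (a config switch can fold the other regions into the
denominator of the proportion score).

## Per-bin model and divergence point

For one (session language, condition) cell and one 20-ms bin, the
target/distractor counts per cluster are modelled as binomial with
logit p = β₀ + random intercept(s); clusters are participants, optionally
crossed with items. The marginal likelihood is Laplace-approximated.
Numerically, we follow the standard profiling scheme used by mixed-model
packages rather than a joint quasi-Newton over (β₀, log σ): for fixed
variance(s) the fixed intercept and all random effects are maximized
together by damped Newton (penalized IRLS; gradient tolerance 1e-10,
backtracking halving), and the Laplace profile deviance — which adds half
the log-determinant of the random-effects block of the penalized Hessian —
is minimized over log σ by bounded scalar search (one variance) or
Nelder–Mead (two variances), starting at σ = 0.1 with log σ ∈
[log 1e-4, log 5]. Everything is deterministic: fixed starting values, no
randomization. The Wald standard error of β₀ comes from the full
(β₀, u)-block of the penalized Hessian at the optimum, conditional on the
estimated variances, as in lme4.

Degenerate cases, in order of fallback: a variance estimate at the zero
boundary collapses exactly to the closed-form pooled GLM
(β₀ = ln(Σtarget/Σdistractor), se = √(1/Σtarget + 1/Σdistractor));
non-convergence with participant+item effects triggers a participant-only
refit, then the pooled GLM; complete separation (all samples on one
picture) is non-estimable and carries p = 1 with a warning; empty bins are
kept in the testing family with p = 1. Every bin records which route fitted
it (`method`), and the pipeline manifest aggregates these provenance
counts.

P-values are corrected with Benjamini–Hochberg (Bonferroni and uncorrected
available) over the family of all 175 bins of the extended window within
one language × condition analysis. The divergence point is the earliest bin
with adjusted p < α (default 0.05) and β₀ > 0; ties and equal p resolve to
the earliest bin. A `min_run` knob (default 1, i.e. the literal
first-significant-slot rule) requires a run of consecutive significant bins
and exists for sensitivity analysis — see Limitations.

The per-bin test is target-vs-distractor *within* a condition, not a
condition interaction: this matches reporting a separate z per condition
and allows the neutral condition to show its own (noun-driven) divergence
after the noun.

## Curves, scores, correlations

Fixation curves: per participant, trials are pooled within each bin and the
percentage per AOI computed; the mean and a normal-approximation 95% CI are
then taken across participants (the participant, not the trial, is the unit
of variation; with fewer than two contributing participants the CI is
empty). Percentages over the four AOIs sum to 100 in fully covered bins.

Predictive ability per participant × language is the constraining − neutral
difference in target fixations inside the critical window. The default
normalization is the mean target-sample count per retained trial, because
pointing exclusions leave different children with different trial counts
and a raw count would confound data quantity with prediction; `raw_count`
(the literal difference) and `proportion` modes are provided, and the run
manifest records the mode used. Correlations with same-language and total
(sum of both languages) CDI scores use tie-corrected Spearman rank
correlation with the t-approximation (n − 2 df) for p; an exact permutation
p is available for n ≤ 10.

## Synthetic-data generator

The generator emulates the assumed study: 17 children × 2 session languages
× 14 trials (7 constraining / 7 neutral, item-condition mapping fixed,
presentation order randomized per participant), 250 Hz over 8-s trials,
~9% incorrect-pointing trials generated with no target preference, and CDI
scores drawn from zero-truncated normals (Norwegian 549.41 ± 95.54,
English 217.56 ± 156.97; truncation shifts the English mean up by ~25
words, which the tests account for).

Per sample the AOI is a categorical draw: the fixation-picture probability
starts at 0.7 and decays exponentially (τ = 1.5 s, floor 0.1) after audio
onset; 5% of mass falls outside every region; the rest splits
target/distractor by p_target(t), which sits at 0.5 until the
participant-specific onset (condition onset + a N(0, 150 ms) shift shared
across that participant-language's trials) and then ramps logistically
(rate 0.01/ms) to 0.85. A per-participant-language preference term
(SD 0.3 on the log-odds scale) adds stable individual bias; the neutral
condition's onset defaults to noun onset + 300 ms, i.e. no prediction, only
noun-driven orienting. Event types are 85% fixation / 10% saccade / 5%
other. When a vocabulary-onset coupling ρ is requested, the onset shift is
built from the same standard-normal draw as the same-language CDI score so
that larger vocabularies mean earlier onsets.

Draws are i.i.d. across samples given these probabilities — there is no
gaze-persistence model (an optional first-order `stickiness` parameter
exists for sensitivity checks, off by default). This is the main
deliberate unrealism: real fixations last hundreds of ms, so real bins are
strongly autocorrelated and carry far fewer effective observations.
Consequently, passing tests on this generator demonstrate the pipeline's
correctness and calibration under the binomial assumptions the per-bin
model itself makes — not the effective power or false-alarm geometry of
real autocorrelated gaze. Each participant consumes an independent Philox
stream spawned from the master seed, so adding participants never perturbs
existing ones and datasets regenerate bit-for-bit from (config, seed).

## Verification experiments

`vwpa.experiments` ships the two simulation experiments the acceptance
script runs. Both analyze with a participant-only random intercept: the
generator has no item effects, so that is the correctly specified model
(the shipped default for real data remains participant+item).

*Null calibration* (200 replicates): flat-chance data (p_target = 0.5
throughout, no heterogeneity). Under the global null BH controls the
familywise error, so a critical-window divergence should appear in ≤ ~5% of
replicates; observed rates sit at or below that band.

*Onset recovery* (20 replicates): a step to the 0.85 asymptote at 1,000 ms
after the verb, with no onset jitter — a sharp step is the only shape for
which "the estimator must not fire before the true onset" is well-posed,
because with mean-zero onset jitter the population curve genuinely rises
before the nominal onset. Detections of the step itself are exact (the
median estimate is 1,000 ms, the bin containing the step); see below for
why a minority of replicates nevertheless report an earlier bin.

## Limitations

**The first-significant-bin rule inherits an early-false-alarm mode from
FDR under strong effects.** With ~115 post-onset bins at astronomically
small p, the BH step-up raises the effective threshold for the ~35
pre-onset null bins to roughly α·k/m ≈ 0.03, so each null bin is promoted
(in the positive direction) with probability ~1.6% and an early false
divergence occurs in a substantial minority of replicates (~40% under the
recovery conditions above) even though the all-null false-alarm rate is
controlled. On real, autocorrelated gaze this mode is much rarer because
adjacent bins are not independent chances. Requiring two consecutive
significant bins (`min_run=2`) suppresses isolated promotions almost
entirely (~1% of replicates) at the cost of departing from the literal
first-significant-slot definition; it is exposed for sensitivity analysis
and used in the test suite where a location property (onset monotonicity)
would otherwise be masked by this mode.

**Attenuation caps the vocabulary-coupling correlation.** With a
vocabulary-onset coupling of ρ = 0.8 and the study-scale onset SD of
150 ms, the per-trial binomial noise caps the attainable score-vocabulary
Spearman correlation near 0.45; the coupling-recovery test therefore runs
the channel at an onset SD of 300 ms (and no preference noise), where the
expected correlation clears 0.5 comfortably.

**No divergence-point uncertainty.** The estimator returns a point, not an
interval; bootstrap uncertainty is out of scope here.

**Other non-goals.** No gaze-event detection (event types are taken from
the input), no interpolation or drift correction, no proprietary tracker
formats, no conceptual-vocabulary scoring, and no smoothing of fixation
curves.
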