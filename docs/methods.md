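# Methods

This note documents the models, analysis rules and numerical choices behind
`cplearn`, the assumptions of the synthetic-data generator, and the points at
which a genuinely open design question was settled by a package-level
decision.

## Texture stimuli

The canonical texture is a 30×30 grid of 6×6-pixel tiles, i.e. a 180×180
binary raster of 900 tiles, optionally resized to 275×275 with a smooth
(Lanczos) resampler for display. Twelve tile patterns are generated
pseudo-randomly under the constraint of exactly 18 black and 18 white pixels
each, with duplicate patterns redrawn; they are paired deterministically
(tiles 2i, 2i+1 form pair i). The analysis pipeline consumes only tile grids
and polarity vectors, never resized pixels, so the choice of resampler is
cosmetic.

Category structure lives entirely in the polarity vector. A `FeatureScheme`
fixes one arbitrary set of k covariant pairs and, per pair, which polarity
signals category K; a texture of category c sets covariant entries from the
scheme and draws the non-covariant entries as fair coins, per stimulus (each
texture contains exactly 6 tile types). Tile placement is an exact-count
balanced permutation — each selected tile type occupies exactly 150 cells —
rather than i.i.d. sampling with replacement: equal representation is treated
as a hard per-stimulus constraint, and spatial arrangement is uniformly
random so position carries no category information. Consequences that the
tests verify: every raster has exactly 16,200 black pixels; with k ≥ 1 a rule
reading covariant polarities classifies perfectly; with k = 0 no polarity is
informative.

Schedules allocate each of the `n` stimuli 2 or 3 presentations: exactly
`n_trials − 2n` stimuli (40 of 180 at the default 400 trials) are drawn
without replacement for a third showing, and the multiset is uniformly
shuffled. Rating pair sets contain 10 K–K, 10 L–L and 20 between-category
pairs, none repeated, in a seed-determined order that is identical pre and
post by construction.

All generators fan a single master seed into named `SeedSequence` substreams,
so any individual object (one stimulus, one subject's log) is reproducible
without regenerating anything else.

## Learning curves and the learner taxonomy

Accuracy is summarized over consecutive *non-overlapping* 20-trial windows
(a sliding variant was considered and rejected: the blocky per-run curves the
taxonomy was designed around are tiled, and tiling keeps the learning point
well defined; `width` is a parameter throughout). The classifier finds the
longest suffix of windows at or above the 80% criterion; if that suffix
covers at least 60 trials, the subject is a Learner with the learning point
at the *first trial* of the suffix's first window (the alternative — the
trial achieving 16/20 within that window — is not used; the window start is
the only unambiguous choice once runs are tiled). A suffix starting at
window 1 makes the subject Immediate (no before-learning trials, hence
excluded from before/after ERP contrasts). Otherwise: Borderline if any
single window touched the criterion, Non-Learner if none did. "Accuracy
around chance" is deliberately not a numeric rule; never-reaching-criterion
is the operative definition.

Before/after trial splits: Learners split at the learning point; Borderlines
and Non-Learners split at the session midpoint, which controls for
mere-exposure and repetition effects in the ERP contrast.

## CP statistics, effect sizes, correlations

Per subject, `Wpre/Wpost/Bpre/Bpost` are plain means of the 20 within and 20
between ratings per phase; `diffW`, `diffB` and `GlobalCP = diffB − diffW`
follow algebraically (an identity the property tests enforce exactly).

Paired effect sizes are standardized on d = t/√(df+1), equivalent to
mean(diff)/sd(diff) on raw paired samples; both paths are implemented and
cross-checked against each other. Spearman correlations use mid-rank ties
(scipy); the Fisher interval is tanh(z ± 1.96/√(n−3)) with z = atanh(ρ). A
constant input series raises rather than returning NaN.

## ERP measurement

Epochs span −1000…+2000 ms around stimulus onset at 500 Hz (synthetic data is
generated at that rate directly; EDF import resamples and band-passes 3–100
Hz with a 60 Hz notch, zero-phase IIR, via the optional mne dependency).
Baseline correction subtracts each trial's per-channel mean over −200…0 ms.

Artifact rejection applies, in order, (1) an extreme-value filter removing
trials with any |sample| > 100 µV on any channel, then (2) a
joint-probability filter. The probability statistic is defined precisely
here, since upstream toolbox internals are not a published algorithm: per
channel, each sample is z-scored against the across-trial distribution at
that sample; the per-trial per-channel statistic is the mean Gaussian
negative log-probability z²/2 over samples, z-scored across trials within
channel; the global statistic is the across-channel mean, z-scored likewise.
The `single_sd` limit (default 2) is interpreted as a *trial-level* two-sided
Gaussian exceedance level, and the per-channel cut is Šidák-corrected for the
montage size: a naive any-channel-over-2-SD rule would reject ≈20% of clean
Gaussian trials on a 10-channel montage purely by familywise growth, whereas
the corrected rule holds the null rejection rate at ≈4.6%, inside the 5–7%
regime observed for filters of this kind; genuine outliers exceed the cut by
an order of magnitude either way. The `global_sd` limit (default 6) applies
uncorrected to the single global statistic. The filter is validated by
constructed-outlier oracles and its own Monte-Carlo null, not by
bit-equivalence with any external toolbox.

Condition averages use only retained trials, indexed by original trial
number; a subject losing more than 20% of a condition's trials is flagged
for exclusion (`SubjectExcluded`). Component measures are plain means over an
electrode cluster and a half-open time window computed by sample-index
arithmetic (no floating-point window fuzz): N1 defaults to 150–220 ms over
(Iz, Oz, O1, O2, POz), LPC to 600–800 ms over (Pz, P1, P2, CPz). Both window
bounds and clusters are configuration, and alternative published cluster
presets (including an 8-electrode parietal set and a 500–800 ms LPC window)
ship in `CLUSTER_PRESETS`; the defaults follow the results-section clusters,
restricted to the synthetic montage for the LPC. `component_mean` is linear
in the waveform, which the tests exploit.

## The two-phase net

Stimuli are binary N-vectors (±1-coded internally) with k covariant
dimensions set by the label and N−k fair coin flips. The model details left
open by its published sketch are fixed as: tanh hidden units (the required
(−1, 1) activation range), a linear reconstruction head for the unsupervised
phase and a linear ±1-target category head for the supervised phase,
full-batch gradient descent, and L2 weight decay as the "regularized" term.
The supervised phase fine-tunes the encoder by default (`finetune_encoder`
flag to freeze it): feature re-weighting in the encoder is the mechanism
under study, so the default lets it happen. The "before" snapshot is the
post-unsupervised state. A net is a Learner iff its final last-layer
regularized MSE is ≤ 10⁻³ (inclusive boundary).

Defaults — n_dims = 12, h = 8, learning rate 0.1, 300 + 300 epochs, L2 10⁻⁵,
40 training and 40 probe items per category — are desk-scale choices (one
fit ≈ 0.1 s). The epoch budget is deliberately finite: with it, learner
fraction rises from ≈0.5 at k = 3 to ≈0.9 at k = 6 over 20 seeds, i.e. a
fixed training budget produces a mix of learner and non-learner nets whose
success depends on the proportion of irrelevant variation — the regime the
human task occupies. Probe sets must share the training set's covariant
scheme (dimensions and polarities) while resampling the irrelevant
dimensions; `gen_binary_stimuli(..., scheme_from=train)` enforces this.
Hidden-space distances are mean pairwise Euclidean distances, computed via
`pdist` and verified against a brute-force double loop. Salience is the
Euclidean norm of each input dimension's encoder weight row.

## Synthetic cohorts: what they emulate and what they do not

Trial logs: correctness is Bernoulli(p(t)) with
p(t) = 0.5 + (a − 0.5)/(1 + e^{−(t−t0)/s}); archetypes fix (t0, s, a)
(Learner: 150/15/0.96; Immediate: −50/10/0.95; Borderline: 120/20/0.78;
Non-Learner: 200/30/0.55). Reaction times are lognormal with the median
declining along the same logistic from 1.1 s by 0.3 s. Ratings: pre = base
mean + N(0, 1) noise, rounded and clipped to 1…9; post adds the injected
σ_B (between) or σ_W (within). Archetype defaults mirror the regimes the
generator emulates: learner σ_B = +1.8, σ_W = −0.43 over base means
5.04/4.01; non-learner σ_B = +0.776, σ_W = +0.376 over 4.87/4.55. Epochs:
white Gaussian noise (SD 10 µV) plus a negative Gaussian N1 template
(center 185 ms, σ 25 ms, peak −4 µV) on the occipital channels and a positive
LPC template (center 700 ms, σ 80 ms, peak +2 µV) on the parietal channels;
from the learning point onward the N1 attenuates by +1.1 µV and the LPC grows
by +0.5 µV for learning archetypes. Artifacts (50-sample 150–300 µV
excursions on one channel) occur at rate 0.06 per trial. The default montage
is 10 named electrodes covering the occipital and parietal clusters plus Fz —
a deliberate reduction from a full 64-channel cap for desk-scale speed
(configurable).

Because templates are Gaussian, the expected window-mean measurement is the
injected peak amplitude times an attenuation factor computed in closed form
(`template_window_mean`), which is what recovery tests assert against.

What the generator does *not* emulate: 1/f background spectra, channel
covariance, eye-blink topographies, between-subject latency jitter of the
components, and any dependence of single-trial EEG on the particular
stimulus shown. Passing recovery tests therefore demonstrates that the
estimators are unbiased and correctly wired under the stated noise model —
not that they are robust to every property of real recordings.

Cohorts draw per-subject profiles around archetype means (jitter on onset,
asymptote and injected effects; `profile_spread=0` yields identical subjects
for exact recovery checks) with largest-remainder apportionment of the
archetype mix. Ground-truth labels travel with every generated object.

## Problem sizes and determinism

The shipped test suite and demo pipeline run at reduced scale chosen as the
smallest sizes at which each statistical check is stable: 40–180 stimulus
sets, 8–50 synthetic subjects, 400-trial epoch sets only where component
recovery is itself under test, 12–20 net seeds per condition. Every stochastic
test fixes its seeds (hypothesis suites are derandomized); the acceptance
script takes a single `--seed` and derives all substreams from it. Reported
pipeline numbers are exactly reproducible from the manifest's seeds.

## Known limitations

- The ERP stage starts from epoched data; continuous-recording preprocessing
  (ICA artifact removal, bad-channel interpolation, re-referencing) is
  assumed done upstream and is out of scope beyond the optional EDF import.
- Repeated-measures/mixed ANOVAs of the original analyses are not
  re-implemented; standard statistics packages cover them.
- The probability filter is *a* precise formalization of a joint-probability
  criterion, not a reimplementation of any specific toolbox's internals.
- The net model makes no claim about absolute distance magnitudes; only
  signs, orderings and their statistical reliability across seeds are
  meaningful, and figure-level curves are qualitative.
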