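# Methods

This note documents the models, the tunable parameters and the numerical
and design choices behind `somnoscore`, at the level a maintainer or a
methodologically minded user needs.

## Scope and assumptions

The scorer operates on 30-s non-overlapping epochs counted from the start
of the recording; a trailing partial epoch is discarded. Stages use the
fixed canonical order (W, N1, N2, N3, R) in every vector and matrix, and
argmax ties break toward the earlier stage in that order (ties are rare and
logged). Emission models are time-independent: the probability of a
feature value given a stage does not depend on where in the night the epoch
sits. Temporal structure enters only through the forward/backward
recursions.

## Feature extraction

* **EEG band powers** integrate the periodogram over δ 0–2.5, θ 2.5–6.8,
  α 6.8–14, β 14–35 Hz. These edges deliberately deviate slightly from
  textbook band definitions; they are the edges the downstream features are
  defined on. A sampling rate of at least 70 Hz is required so β stays
  below Nyquist.
* **ORP-style stage likeliness** is a rank-based approximation: each 3-s
  window's four band powers become within-recording decile ranks, the four
  digits form a signature, and a lookup table maps each signature to the
  stage frequencies observed among labelled training windows. Epoch score =
  mean over its ten windows; unseen signatures back off to the training
  stage priors. The scores are independent likelinesses in [0, 1] and do
  not sum to 1 across stages. The original odds-ratio-product algorithm is
  proprietary; this re-implementation keeps its substance (ranked band
  powers → wake/sleep-depth likeliness) with a transparent estimator.
* **Spindles**: the epoch is band-passed 9–17 Hz (4th-order zero-phase
  Butterworth) and partitioned at zero crossings. The band-pass is this
  package's design choice: a 4 µV spindle burst is invisible to
  zero-crossing analysis under an 80 µV slow background, and the scoring
  bands below make the detector selective again after filtering. Crossing
  positions are linearly interpolated between samples — at 100 Hz,
  whole-sample crossings would quantise a 13 Hz wave onto 12.5/16.7 Hz and
  inflate the frequency variance. Each segment of duration d (equivalent
  frequency f = 1/(2d)) and peak amplitude a is scored by two
  piecewise-linear functions — frequency score 1 on [12, 14) Hz, falling to
  0 at 10.5 and 16 Hz; amplitude score peaking at 4 µV and 0 from 12 µV —
  and by the *spindle factor*: the variance of the frequencies in the ±5
  neighbouring segments (truncated at epoch edges) divided by the product
  of the two scores (+∞ when either score is 0). The factor is a ratio
  because it must be *low* for spindle-like segments: low local frequency
  variance, high scores. Maximal runs of segments with factor below the
  threshold (default 1.0 Hz², configurable) lasting ≥ 0.5 s count one
  spindle each.
* **Eye movements**: both EOG channels are band-passed 0.3–10 Hz; half-waves
  between baseline crossings with amplitude ≥ 25 µV are candidate
  deflections. Conjugacy — the two periorbital electrodes see mirrored
  potentials when the eyes move together — requires temporally overlapping,
  opposite-signed half-waves on the two channels. The initial deflection's
  duration classifies the event: < 0.5 s with peak slope > 1 µV/ms ⇒ REM;
  > 0.5 s ⇒ SEM. The thresholds are configurable; they operationalise a
  textual description whose reference implementation is unavailable.
* **Background EMG**: mains notch (49–51 Hz by default, 59–61 Hz
  selectable), band-pass 10–100 Hz (capped at 0.45·fs), rectification into
  a 50 ms envelope, then a morphological opening with a flat 0.5-s
  structuring element — the opening removes brief bursts (swallowing,
  movement) and keeps the tonus floor. Epoch means are averaged over
  channels and divided by the recording median, so the median epoch is
  exactly 1. The envelope step stabilises the opening on noise (without it
  the opening tracks a rolling minimum, giving ±15% epoch noise on
  stationary input).
* **Heart rate** is used as a within-recording mid-rank quantile,
  (rank − 0.5)/n, because absolute rate is strongly person-dependent;
  the epoch-to-epoch change is kept as a second coordinate. Per-epoch rates
  are the preferred input; an R-peak counter for raw ECG exists as a
  convenience only.
* **SaO₂** samples below 50% are treated as sensor dropout and excluded
  before the epoch mean and population variance; an all-dropout epoch
  yields missing values, which the emission layer maps to uninformative
  (uniform) emissions.
* **Snores** come from an event list when available; the microphone path
  (supra-threshold envelope bursts of 0.1–2 s, threshold 3× median
  envelope) is a deliberately simple stand-in.

## Emission models

Each feature group x is replaced by the five normalised stage-conditional
densities `e_s(x) = p(x|s) / c_x` with `c_x = Σ_t p(x|t)`, so each group's
five values sum to exactly 1. The unweighted sum over stages is the only
normaliser for which this holds identically; it equals the stage posterior
under a uniform prior, and deliberately removes the rarity of x itself from
the feature.

Families, with their free parameters per stage:

* **Histogram** (snores, position change): add-one-smoothed normalised
  histogram on {0..support_max}; larger counts clamp into the top bin.
* **Spindle counts** given spindle density ρ: negative binomial with mean
  `aρ^b` and variance `aρ^b + cρ^d`; c = 0 recovers the Poisson limit,
  negative c (variance below mean) is rejected.
* **REM counts** (truncated at 3) given REM density: unnormalised weight
  `a_x / (a_x + ρ^(−b_x)) = σ(b_x ln ρ + ln a_x)` per count value,
  normalised over x at the observed ρ. The printed source for this family
  is typographically ambiguous; this reading is isolated in one function
  (`_rem_unnorm`) so an alternative can be swapped in wholesale. Once
  normalised, the family has a near-flat direction (for small occupancies
  the sigmoids degenerate to a softmax, which is invariant under a shared
  rescaling of a and shift of b), so the x = 0 category is pinned at
  a₀ = 1, b₀ = 0 and six parameters are fitted.
* **SEM counts** (0/1) given SEM density: log-linear `exp(a_x + b_x ρ)`,
  which after normalisation is a logistic regression on ρ; only the
  differences a₁−a₀, b₁−b₀ are identified, so x = 0 is pinned at 0.
* **Background EMG**: two-branch power law `p(x) = x^a / c` for x < 1 and
  `x^(b−2) / c` for x ≥ 1 with `c = 1/(a+1) + 1/(1−b)`, valid for a > −1,
  b < 1. The second branch's exponent is written b−2 because the naive
  exponent −b with b < 1 does not integrate; b−2 reproduces the stated
  normalising constant exactly and keeps the power-law decay. The density
  peaks at the median value 1 whenever a > 0.
* **1-D / 2-D KDE** (ORP scores; heart-rate pair; SaO₂ pair): Gaussian
  kernels with Scott's-rule bandwidth, evaluations floored at 1e−12; 2-D
  fits require ≥ 30 samples per stage.

The default layout is 13 groups (5 ORP + spindles + REMs + SEMs + EMG +
heart rate + SaO₂ + position + snores) = 65 emission values per epoch. The
group list is configurable. ρ values are constant within a recording;
joint families are normalised over the count conditional on ρ, with the
ρ-marginal absorbed into the constant — sufficient because only stage-wise
ratios at the observed (x, ρ) matter after normalisation.

Maximum-likelihood fits use bounded L-BFGS-B with 5 starts (fixed seeds)
and tight tolerances (ftol 1e−12). Degenerate SEM samples (all-0 or all-1)
saturate the intercept instead of failing.

## Sequence classifier

Three random forests (default: 100 trees, unlimited depth, min-leaf 5, √d
features per split, all configurable) share the leaf-fraction probability
estimate: per tree, the fraction of training instances of each class in the
leaf containing the input, averaged over trees.

* The **forward** transition forest maps (one-hot previous stage, e_t) to
  the current stage; the **backward** forest conditions on the next stage.
  Two separate forests are used rather than one shared model because the
  two conditional distributions are different objects.
* At inference the recursion's sum over the conditioning stage is computed
  *exactly*: the forest is evaluated on all five one-hot inputs per epoch
  and the outputs mixed by the incoming distribution (no sampling, no
  approximation). α₀ is the empirical first-epoch stage distribution of
  the training set; β_{n+1} defaults to the empirical last-epoch
  distribution (symmetric choice) and can be set to uniform.
* The final forest sees `x_t = [α_{t−1}, e_t, β_{t+1}]` (75 values at the
  default 13 groups). Training-time α/β are produced by the same recursions
  used at inference — no teacher forcing — so the feature distribution the
  final forest sees matches deployment.
* All randomness derives from one seed (spawned per component), every
  forest runs single-threaded, and identical seeds give bit-identical
  models and predictions.
* Grouped feature importance sums mean-decrease-impurity importances within
  each block (α, each emission group, β); fractions sum to 1.

An `temporal_context=False` ablation trains the final forest on the
emission vector alone; it exists so the value of the α/β context is
measurable.

## Certainty transform

* **Smoothing**: the candidate is the 3-epoch moving average (boundary
  epochs average the two available values — no values are invented outside
  the recording). N2/N3/R always take the candidate; W and N1 take it only
  if it reduces the raw value by less than one third, because brief
  awakenings and arousals are real sharp events that smoothing would
  erase. A raw value of 0 always accepts the candidate. All stages are
  smoothed from the same raw track, so stage order cannot matter.
* **Exclusion**: a stage with a competitor at least 3× more likely is
  zeroed (with a relative epsilon so exact 3:1 boundaries are excluded).
  After exclusion, surviving values within a row are always within a
  factor 3 of each other, which makes exclusion + renormalisation
  idempotent.
* **Categories**: 1 / 2 / ≥3 surviving stages ⇒ certain / doubt /
  uncertain. The expert-side transform applies exclusion and
  renormalisation to the per-epoch rater fractions — no smoothing, since
  rater panels are already per-epoch aggregates.
* **Doubt guidance**: for each maximal doubt run between two certain
  flanks — differing flanks (transition): recommend the first epoch where
  the rising stage's p* overtakes the falling one's; equal flanks
  (excursion): recommend the epoch where the minority stage's p* peaks.
  Runs touching the recording edge or an uncertain block get no
  recommendation. Both 1/3 thresholds (smoothing guard, exclusion ratio)
  are configuration values.

No probability calibration is applied; the transform trades calibrated
magnitudes for interpretable between-stage ratios by design.

## Evaluation machinery

Confusion matrices are 5×5 percentage tables, rows = expert, columns =
algorithm. Multi-rater matrices weight every epoch equally: 1/C(m,2) per
unordered rater pair (pairwise matrix, folded to the upper triangle because
rater order is arbitrary) or 1/m per rater (panel vs prediction). Accuracy
and IRR are traces; Cohen's κ uses the matrix marginals (on weighted
matrices this is an extension of the single-rater definition and is flagged
as such; it is undefined on the folded pairwise matrix). Statistics are
computed on unrounded cells and displayed to one decimal; published
percentage tables (which may total a few tenths off 100 due to rounding)
are accepted directly as inputs via `ConfusionMatrix.from_table`.

The certainty cross-tab counts epochs per (expert category × model
category) cell with per-cell correctness: certain/certain — predicted stage
equals the consensus; certain/doubt — consensus among the model's two
candidates; doubt/certain — prediction among the experts' two candidates;
doubt/doubt — identical candidate pairs; uncertain rows report fractions
only. The reliability curve sorts epochs by the top posterior and takes
moving averages (default window 1000) of correctness, expert certainty and
model certainty over that order. Hypnodensity figures stack per-epoch stage
probabilities as coloured bands (W yellow, N1 brown, N2 blue, N3 black,
R red).

## Synthetic data: what it emulates, and what it does not

The simulator draws stage sequences from a first-order Markov chain whose
default transitions are hand-set for sleep-like persistence
(self-transitions ≥ 0.88 for N2/N3/R, brief wake intrusions) with a
stationary mix near W 22 / N1 9 / N2 39 / N3 16 / R 14 % — a loose match to
clinical sleep-lab populations, stated as a target, not a claim. Feature
draws use exactly the stage-conditional families the emission layer fits,
with per-recording event densities from log-normal hyper-distributions
(spindles ln 1.2 ± 0.4, REMs ln 0.8 ± 0.5, SEMs ln 0.3 ± 0.5) so the joint
count/density families see realistic between-patient variation. ORP scores
are drawn with mean 0.65 for the matching stage vs 0.35 otherwise
(sd 0.18, clipped to [0, 1]) — informative but noisy single-epoch evidence,
so temporal context genuinely helps. Rater panels push the true stage
through a confusion matrix with ~0.9 diagonal and mass on the clinically
confusable pairs (W↔N1, N1↔N2, N2↔N3), giving a pairwise agreement near
0.81.

Because features are drawn from the very families the emissions fit, a
passing end-to-end run shows the pipeline's machinery is correct and
self-consistent — it does *not* show that the families fit real
polysomnograms, that real features are conditionally independent given the
stage, or that real inter-rater disagreement is symmetric and
epoch-independent like the confusion-matrix raters. Signal-level
simulation covers only what the detectors need (injected 13 Hz / 4 µV / 1 s
bursts, sharp and slow conjugate EOG deflections, stage-scaled EMG noise);
it is not physiologically realistic EEG.

Problem sizes used by the test suite and the acceptance script: the
end-to-end run trains on 20 recordings × 960 epochs (a 20-night,
8-hour-per-night training set) with one held-out recording; recovery
experiments use 50,000 draws per family (100,000 for moment checks);
detector fixtures use 80 clean N2 epochs. The REM-joint recovery
experiment uses a wider density spread (lognormal sd 1.0) and steeper
occupancy slopes than the generator defaults: a Fisher-information analysis
showed the 15% recovery bar sits below one standard error under narrower
spreads, i.e. the narrow design cannot resolve the parameters at that
sample size.

## Known limitations

* Eight detector thresholds (spindle factor threshold, EOG amplitude/slope
  cuts, EMG cutoffs, SaO₂ dropout level, snore envelope rule) are declared
  approximations of descriptions whose reference implementations are
  proprietary or unstated; all are configuration values.
* The stated emission-feature total in the source material (60) cannot be
  reconciled with its own feature list; this implementation's default is 13
  groups × 5 = 65, and the group list is configurable.
* Certainty probabilities are deliberately uncalibrated.
* Cohen's κ on epoch-weighted multi-rater matrices is a flagged extension.
* The EDF writer covers plain EDF with 16-bit records — enough to
  round-trip simulated recordings; clinical EDF+ annotations are not
  written.
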