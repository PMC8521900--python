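# somnoscore

Automated sleep-stage scoring for polysomnography (PSG) with explicit
prediction certainties, plus the multi-rater evaluation machinery needed to
judge such a scorer against panels of human experts.

## The problem

Sleep studies are scored by experts who assign one of five stages — W
(wake), N1, N2, N3 (light to deep non-REM) and R (REM) — to every 30-second
epoch of an overnight recording, following the AASM manual. Manual scoring
is slow, and two experts given the same night agree on only ~85% of epochs.
An automated scorer is therefore most useful when it (a) mirrors the
interpretable AASM-style features experts already reason with, and (b) says
*when it is unsure*, so experts need to review only a small fraction of the
night.

## The model

`somnoscore` scores a recording in four steps:

1. **Feature extraction** — per-epoch AASM-style features: ORP-style stage
   likelinesses from ranked EEG band powers (δ 0–2.5, θ 2.5–6.8, α 6.8–14,
   β 14–35 Hz); sleep-spindle counts from a zero-crossing segment detector
   with piecewise-linear frequency (peak 12–14 Hz, zero at 10.5/16 Hz) and
   amplitude (peak 4 µV, zero at 12 µV) scores and a local
   frequency-variance "spindle factor"; rapid/slow conjugate eye-movement
   counts (REM < 0.5 s initial deflection, SEM > 0.5 s); background EMG
   (filtered, morphologically opened, median-centred); heart-rate quantile
   and change; SaO₂ mean/variance; body-position changes; snores.
2. **Emission modelling** — each feature group x is replaced by its
   normalised stage-conditional densities
   `e_s(x) = p(x|s) / Σ_t p(x|t)`, which sum to 1 over stages (the
   posterior under a uniform prior). Count features that depend strongly on
   the patient (spindles, REMs, SEMs) are modelled jointly with their
   per-recording densities ρ: a negative binomial with mean `aρ^b` and
   variance `aρ^b + cρ^d` for spindles, sigmoid-in-ρ occupancy curves for
   REMs, a logistic in ρ for SEMs. Background EMG follows a two-branch
   power law peaking at the median; continuous pairs use 2-D Gaussian KDEs.
3. **Sequence classification** — a random forest predicts the stage of
   epoch t from `x_t = [α_{t−1}, e_t, β_{t+1}]`, where the forward/backward
   stage distributions are propagated by classifier-estimated transition
   kernels: `α_t(s) = Σ_k P(s_t=s | s_{t−1}=k, e_t) α_{t−1}(k)` and its
   mirror image. Class probabilities are leaf-fraction estimates averaged
   over trees.
4. **Certainty transform** — posteriors are smoothed (3-epoch moving
   average; W/N1 jumps protected), stages at least 3× less likely than a
   competitor are zeroed, and the survivors renormalised (p*). One
   surviving stage ⇒ *certain*; two ⇒ *doubt* (both candidates reported);
   three or more ⇒ *uncertain*. Doubt runs between certain flanks come with
   review guidance: score the crossing epoch of a transition, or the
   minority-probability peak of an excursion.

The same transform applied to the fraction of raters voting each stage
gives the expert-side certainty, enabling a category-by-category accuracy
cross-tab, epoch-weighted confusion matrices (pairwise between raters, and
panel-vs-algorithm), inter-rater reliability (IRR), Cohen's κ, reliability
curves and hypnodensity plots.

A built-in simulator generates Markov stage sequences with sleep-like
architecture, per-epoch features drawn from the same stage-conditional
families, raw signal snippets with injected spindles and eye movements, and
multi-rater panels via a rater-confusion matrix — so the entire pipeline is
testable without clinical data.

## Worked example

```python
import numpy as np
from somnoscore import (GeneratorConfig, SleepStager, CertaintyTrack,
                        simulate_dataset)
from somnoscore.certainty import doubt_guidance

config = GeneratorConfig(n_psgs=6, n_epochs=200, seed=11)
features, stages = simulate_dataset(config)

model = SleepStager(n_estimators=30, random_state=5).fit(features[:5], stages[:5])
print("held-out accuracy:", round(model.score(features[5], stages[5]), 3))

probs = model.predict_proba_sequence(features[5])
track = CertaintyTrack.from_raw(probs)
counts = {c: track.category.count(c) for c in ("certain", "doubt", "uncertain")}
print("certainty categories:", counts)
print("doubt runs flagged for review:", len(doubt_guidance(track)))
```

prints

```
held-out accuracy: 0.88
certainty categories: {'certain': 137, 'doubt': 40, 'uncertain': 23}
doubt runs flagged for review: 9
```

i.e. the model scores 88% of held-out epochs correctly, is confident enough
to skip review on 137 of 200 epochs, and narrows 40 epochs to a choice
between two stages, organised into 9 runs each of which an expert can
resolve by scoring one recommended epoch first.

Published percentage confusion matrices are first-class inputs; the derived
statistics come out of the same evaluation code:

```python
from somnoscore.evaluation import accuracy, cohen_kappa, irr
from somnoscore import examples

C = examples.single_scored_confusion()
print(round(accuracy(C), 1), round(cohen_kappa(C), 3))   # 80.5 0.734
print(round(irr(examples.pairwise_expert_confusion()), 1))  # 84.1
```

A command-line surface mirrors the library:

```bash
somnoscore simulate --out data --n-psgs 4 --n-epochs 120 --seed 1
somnoscore train    --data data --out model.joblib --seed 1
somnoscore predict  --model model.joblib --features data/features_003.tsv --out-prefix pred
somnoscore evaluate --pred pred_hypnogram.tsv --raters data/raters_003.tsv --out eval
somnoscore report   --pred pred_hypnogram.tsv --out-prefix rep
```

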