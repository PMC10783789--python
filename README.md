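# copingmanifold

Analysis of prefrontal single-cell calcium dynamics during repeated threat
exposure in a tail-suspension (TS) paradigm.  Mice suspended by the tail
alternate between active coping (struggling) and passive coping (immobility);
1-photon calcium imaging of prefrontal pyramidal cells across repeated
exposures asks whether single-neuron tuning and population geometry are
stable over days and shared across individuals.  The package implements the
full analysis chain for such data — and a synthetic-data generator with known
ground truth, so every stage is testable without any recordings.

## What it computes

For sessions pairing z-scored calcium traces (neurons × frames, 20 Hz) with
frame-aligned behavior (context: baseline/TS; coping: struggle/immobility;
per-body-part speed):

- **Trace conditioning** — running 10th-percentile detrending (30 s window),
  session-wide z-scoring, transient masks (frame-to-frame rise > 2 SD), and
  the Gaussian-smoothing (σ = 250 ms) + quantile scaling (n_quantiles = 100)
  used before embedding.
- **TS selectivity** — per neuron, with the session min-max scaled to [0, 1],

  ```
  score = (m_TS − m_baseline) / (m_TS + m_baseline)  ∈ [−1, 1]
  ```

  (−1: active only at baseline; +1: only under TS; |score| > 0.2 classifies
  a neuron as baseline- or TS-selective), plus a transient-rate variant.
- **Movement tuning** — Pearson r between each trace and the animal's speed
  within a context (|r| > 0.2: struggle- or immobility-tuned), single-variable
  linear-model explained variance with circular-shift surrogate significance,
  and peri-event onset-lag analysis (±0.5 s cross-correlation).
- **Decoding** — class-balanced, 10-fold cross-validated decoding of context
  (logistic, C = 0.1), coping style (logistic, C = 0.01; also linear SVM,
  ridge classifier, Gaussian naive Bayes) and speed (ridge, α = 50), within
  and across conditions and days (via a cross-day registration table), always
  with circular-shift surrogate chance levels and shared fold indices.
- **Manifold analysis** — isomap embedding into 5 dimensions (n_neighbors =
  500, fit on a 60% temporal stride; PCA/spectral as alternatives), flow
  fields (15 × 15 binned velocity vectors) and turn-angle statistics of the
  rotational trajectory, epoch-averaged 5 × 40 **template manifolds** (each
  coping epoch rescaled to 20 progression digits), and **orthogonal
  Procrustes alignment**:

  ```
  Q* = argmin_Q ‖AQ − B‖_F   over orthogonal Q,
  AᵀB = UΣVᵀ  ⇒  Q* = UVᵀ,   aligned manifold = MQ*
  ```

  with Haar-random rotation and circular-shuffle null manifolds, and
  cross-manifold decoding between days or animals.

The generator emulates the study's structure: two contexts with per-neuron
context gain, bout-structured coping whose immobility fraction rises over
days, TS-specific movement coupling, a rotational ring latent spanning the
two coping states, ~40% of cells present on all three days, and multiple
animals sharing one latent law under per-animal orthogonal loading rotations.

## Worked example

```python
import numpy as np
from copingmanifold import GeneratorParams, generate_session
from copingmanifold.tuning import score_session
from copingmanifold.decoding import decode_coping

params = GeneratorParams()              # 200 neurons, 10 min baseline + 10 min TS
session, truth = generate_session(params, day=1, truth=None,
                                  rng=np.random.default_rng(1))

table = score_session(session)
print(table["selectivity_class"].value_counts().to_dict())
# {'none': 137, 'baseline': 40, 'TS': 23}

res = decode_coping(session, n_surrogates=20, rng=np.random.default_rng(1))
print(round(res.mean_score, 3), round(res.surrogate_mean, 3))
# 0.959 0.524
```

About 20% of neurons come out baseline-selective and ~12% TS-selective
(score beyond ±0.2), matching the generator's planted fractions.  The
struggle/immobility state is read out frame by frame at 96% accuracy, while
the same decoder on circularly shifted traces sits at the 0.52 chance level —
the separation the surrogate control is there to demonstrate.

A full study analog (multi-animal, multi-day, with manifold alignment) runs
from the shell:

```bash
copingmanifold simulate --out-dir scratch/demo --animals 2 --days 1,3 --seed 1
copingmanifold report --out-dir scratch/report --animals 2 --days 1,3 --seed 1
```

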