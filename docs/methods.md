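# Methods

## Data model and conventions

A session is one animal-day: a z-scored calcium-trace matrix (neurons ×
frames, 20 Hz) with a boolean transient mask, and frame-aligned behavior
(context baseline/TS, coping struggle/immobility/ambiguous within TS,
per-body-part speed and its mean).  Frames are 0-based; windows are
half-open `[start, end)`; seconds convert to frames by rounding to nearest.
Ambiguous coping frames are stored and excluded explicitly by each analysis
that consumes coping labels, never dropped silently.  Cross-day identity is
a CSV table of global ids versus per-day local row indices with −1 meaning
"not detected that day"; "repeatedly identified" neurons are those present
on every requested day.

Z-scoring is computed once over the concatenated baseline + TS frames, so
scores that compare the two contexts share one scale (a `zscore_joint`
switch exposes the per-segment alternative).  The transient rule reads
"increased by more than 2 SD" as a frame-to-frame increment exceeding 2 SD
of the (z-scored) trace — the reading that yields a per-frame boolean of
rising signal; the level-crossing alternative is noted here as rejected.
The running-percentile detrend uses a centered window with truncated edges.

## Synthetic-data generator

The generator is the package's test bed: it produces sessions whose
statistical structure matches what the analyses assume, with ground truth
attached.

**Behavior.**  A baseline segment (default 12,000 frames = 10 min) precedes
a TS segment (12,000 frames).  TS is tiled with alternating struggle and
immobility bouts drawn lognormal (struggle mean 6 s, log-SD 0.9 — bout
durations in manually scored tail suspension are highly variable, and this
irregularity also prevents circularly shifted traces from staying
phase-locked to a quasi-periodic bout rhythm).  Immobility durations are
rescaled toward the day's scheduled immobility fraction (0.4 on day 1, 0.6
from day 3 — passive coping increases after the first exposure) so the
realized fraction lands within ±0.05.  Two frames at each bout transition
are labeled ambiguous.  Speed is a state-level mean (struggle 8 cm/s,
immobility 0.4, baseline 3) under slow multiplicative noise, per body part.

**Latent.**  A ring phase advances 0 → π across each struggle epoch and
π → 2π across each immobility epoch (one rotation per coping cycle, fixed
direction), with slow Gaussian phase jitter (σ = 0.1 rad, smoothed at 250
ms; unsmoothed per-frame jitter would dwarf the ~0.03 rad/frame clean
increment and destroy the frame-level rotation signature).  Baseline frames
sit near the ring center.  Three nuisance dimensions carry white noise.

**Neurons.**  Rate = `rate_scale · softplus(loadings·latent + β·speed_TS +
bias) · g^[TS]`; Poisson events are convolved with an exponential kernel
(τ = 0.6 s, GCaMP6f-like), Gaussian noise added (SD 0.1), traces z-scored.
Designated fractions (20% baseline-, 12% TS-selective, matching the reported
class proportions) receive strong context gains (median 4× / 0.25×); the
remainder jitter around g = 1.  Movement coupling β is continuous across
the whole population — 15% + 15% strongly tuned (|β| ≈ 1.5), the rest
spread at SD 0.35 — because tuning in real populations is a continuum that
the ±0.2 score threshold cuts; with exact zeros for "untuned" cells a rank
correlation between true and estimated coupling would be tie-dominated and
uninformative.  β acts only on TS-context speed (coping-specific motion
coding, the structure the cross-condition decoding analysis tests).  Ring
loadings are deliberately modest (SD 0.15 vs 0.35 for the β spread): the
ring's sine component is itself a coping-state signal, and if it dominated,
per-neuron movement scores would measure shared state tuning rather than
each cell's own speed coupling.

**Days and animals.**  One ground truth per animal; per-day presence is
i.i.d. Bernoulli (p = 0.74, giving p³ ≈ 0.405 present on all three days);
present neurons keep their loadings up to a small multiplicative jitter
(log-SD 0.05).  A cohort shares one set of base neuron parameters whose
loadings pass through an independent Haar-random orthogonal mixing matrix
per animal — same latent law, different neural axes, which is exactly the
situation Procrustes alignment is meant to undo.  A `day_drift` knob
(default off) adds a day-dependent mean-rate factor.  All randomness flows
from one master seed through keyed child streams per (animal, day, stage).

**What the generator does not emulate:** imaging noise structure
(neuropil, motion artifacts), non-Poisson firing statistics, slow drifts
(so the percentile detrend is exercised in unit tests, not in the default
pipeline), sub-frame timing, and any true nonlinearity between latent state
and behavior beyond the softplus.  Passing tests therefore demonstrate that
the analysis recovers the planted structure under calcium-like noise — not
that real recordings satisfy the model.

## Scoring and decoding

Selectivity uses the per-neuron min-max scaled concatenated session;
zero-range neurons are flagged as missing, never scored 0.  Classification
boundaries (±0.2) are exclusive.  The transient-based variant uses transient
rates; the rate's time unit cancels in the ratio.

Explained-variance regressions and all decoders use contiguous temporal
blocks as CV folds (frame-shuffled folds are available behind a switch):
with ~1 s calcium kernels, shuffled folds would leak autocorrelated signal
between train and test.  Standardization is fit on training folds only (the
literal "standardize everything first" variant is behind
`standardize_global`).  Binary tasks are class-balanced by subsampling the
majority class, so chance is 0.5 by construction; chance is nevertheless
*reported* from circular-shift surrogates, which rotate each neuron's full
session trace by an independent offset before train/test extraction.
Shifting only the extracted frame subset instead leaves a systematic ≈ +0.05
accuracy bias from session-wide chance correlations that survive within-
subset rotation.  Paired comparisons (real vs surrogate, condition A vs B,
day vs day) share one fold-index template, recorded as a hash on each
result and checked when results are compared.

Surrogate shifts for EV significance are uniform over ±[20 s, 120 s] and
wrap circularly.  The EV significance test is exactly calibrated only when
the null is shift-exchangeable; on very short traces the distinct-offset
space is narrow and smooth EV-versus-offset curves shrink the effective
surrogate sample, inflating the false-positive rate — calibration checks
therefore use ≥ 5 min traces.

The onset-lag (PETH) analysis z-scores each ±0.5 s event window ("per-event
normalization" — the natural reading given no stated definition), averages
over events, and cross-correlates the averaged response with the averaged
speed; lag is the argmax correlation for struggle neurons and argmin for
immobility neurons, significance is a >1 SD deviation (in the tuned
direction) from the distribution of peak correlations across analyzed
neurons of that type.  With one analyzed neuron the SD is undefined and the
result is flagged, not classified.

## Manifold analysis

Embedding operates on smoothed (σ = 250 ms), per-neuron quantile-scaled TS
traces.  Isomap (d = 5, Euclidean) is fit on an evenly spaced 60% frame
subset — an even stride is the deterministic reading of "temporally
downsampled"; a random subsample sits behind a flag — and then transforms
all frames; PCA and spectral embedding fit on everything.

Template manifolds map every struggle epoch onto progression digits 1–20
(evenly spaced start → end, rounding; epochs shorter than 2 frames are
excluded, shorter than 20 frames reuse digits), average per digit and
dimension over all epochs of that class, and concatenate struggle digits
then immobility digits: d × 40 for the defaults.  Manifolds are centered to
their centroid and scaled by the whole matrix's Frobenius norm ("divide by
its norm" read as one global scale; per-dimension normalization is a config
alternative).  For alignment, templates are transposed to time-by-dimension
(40 × d): `AQ` with a d × d orthogonal `Q` forces time along rows, even
though the templates are naturally stored 5 × 40.

The Procrustes solution is the SVD closed form `Q = UVᵀ` of `AᵀB` (singular
values descending), which is the global minimizer of ‖AQ − B‖_F over the
orthogonal group; `Q` is not projected to det +1 (reflections allowed, as
"orthogonal" implies), while the rotation *null* is rotation-only
(Haar-uniform, det +1, 100 repetitions).  Rank-deficient `AᵀB` leaves the
optimum non-unique; the result is flagged, not rejected.  The shuffle null
circularly shifts each neuron's scaled trace and repeats embedding →
template → alignment with the reference manifold held fixed.

Flow fields assign each consecutive-frame velocity to the spatial bin of
the segment midpoint and keep per-bin mean positions: the midpoint
convention makes the mean chord exactly orthogonal to the mean radius on a
circle, so tangency statistics are exact rather than biased by O(step)
chord-versus-tangent misalignment.  Turn angles are computed on the
trajectory mean-binned to 2.67 Hz; angles in (0, π) are leftward.  The
automated rotation-plane selection ranks axis pairs by winding coherence —
|net| / total winding of the centroid-centered position angle, damped below
one revolution and weighted by radius uniformity.  A velocity-turn-angle
criterion was rejected: consecutive white-noise velocities anti-correlate,
piling turn angles near ±π and outscoring genuine slow rotation.

Cross-manifold decoding balances struggle/immobility counts within and
between the two datasets, trains on the reference manifold (logistic
C = 0.01 for coping, ridge α = 50 for speed) and scores on the aligned
target, sharing fold indices across the real, rotation and shuffle variants.
Cross-animal analyses pair animals circularly (train on animal n−1, test on
animal n, wrapping).

## Problem sizes and defaults

The default generator session is 200 neurons × (12,000 + 12,000) frames —
the tuning and decoding analyses run at this size.  Embedding-based runs
(across-day and cross-animal alignment, the pipeline report, the acceptance
script) use 150 neurons × 3,000 TS frames with isomap n_neighbors = 100:
geodesic-graph construction and kernel eigendecomposition dominate runtime,
and the alignment results are unchanged at this scale (n_neighbors follows
the frame count at roughly the paper's neighbors-to-frames ratio).  The
shuffle-null accuracy declines toward 0.5 with session length; at these
sizes it sits near 0.6 — far below real aligned decoding (≥ 0.95) but above
asymptotic chance, because templates averaged over ~25 epochs still let the
alignment overfit weak epoch-locked structure in an autocorrelated null
manifold.

## Known limitations

- The generator's ring latent ties phase to within-epoch progression; real
  trajectories need not parameterize coping this way.
- `ev_significance` assumes stationarity; trends that survive detrending
  will inflate both real and surrogate EVs.
- Spectral embedding has no out-of-sample transform, so its coordinates are
  only comparable within one fit.
- The quantile transform saturates genuinely novel extremes at 0/1 when a
  fitted map is reused.
- Group-level inference (mixed models, repeated-measures ANOVA) is out of
  scope by design: the report exposes per-animal values for downstream
  statistics packages.
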