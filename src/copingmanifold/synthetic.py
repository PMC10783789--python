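"""Synthetic multi-day, multi-animal calcium sessions with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without real recordings:

* two contexts (homecage baseline, then tail suspension) with per-neuron
  multiplicative context gain (g > 1: suspension-preferring, g < 1:
  baseline-preferring);
* bout-structured struggle/immobility behavior in the suspension segment,
  with lognormal bout durations and a per-day immobility-fraction schedule
  that rises after the first exposure (habituation to repeated threat);
* movement-tuned neurons whose speed coupling acts only in the suspension
  context (coping-specific motion coding, not general motion tuning);
* a low-dimensional rotational latent: a ring phase that advances 0..pi
  across each struggle epoch and pi..2pi across each immobility epoch, plus
  white-noise nuisance dimensions;
* partial cell overlap across days (independent per-day presence, default
  p = 0.74, so ~40% of cells appear on all three days);
* multiple animals sharing one latent law under per-animal orthogonal
  rotations of the neuron loadings.

Rates follow a softplus-linear model; calcium-like traces are Poisson events
convolved with an exponential kernel (tau = 0.6 s, GCaMP6f-like decay) plus
additive Gaussian noise, then z-scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.stats import special_ortho_group

from .preprocess import detect_transients, zscore
from .session import (AMBIGUOUS, BASELINE, IMMOBILITY, NOT_APPLICABLE, STRUGGLE, TS,
                      BehaviorTrack, CalciumTraces, RegistrationMap, SessionRecording)
import pandas as pd


class ParameterError(ValueError):
    """Generator parameters are inconsistent or infeasible."""


@dataclass
class GeneratorParams:
    """All knobs of the synthetic-session generator (defaults = study analog)."""

    n_neurons: int = 200
    n_frames_baseline: int = 12000     # 10 min at 20 Hz
    n_frames_ts: int = 12000
    frame_rate: float = 20.0

    # behavior
    struggle_bout_mean_s: float = 6.0
    bout_sigma_log: float = 0.9        # lognormal shape of bout durations
    min_bout_s: float = 1.0
    immobility_schedule: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 3: 0.6, 9: 0.6})
    ambiguous_frames_per_transition: int = 2
    speed_struggle: float = 8.0        # cm/s, mean over struggle frames
    speed_immobility: float = 0.4
    speed_baseline: float = 3.0
    speed_noise_frac: float = 0.25     # multiplicative speed variability
    speed_smooth_s: float = 0.25
    n_speed_parts: int = 4

    # tuning structure
    frac_baseline_selective: float = 0.20
    frac_ts_selective: float = 0.12
    frac_struggle_tuned: float = 0.15
    frac_immobility_tuned: float = 0.15
    gain_strength: float = 4.0         # median |context gain| of selective cells
    gain_log_sd: float = 0.2
    gain_null_log_sd: float = 0.05
    beta_tuned_mean: float = 1.5       # speed coupling of tuned cells
    beta_tuned_sd: float = 0.3
    beta_null_sd: float = 0.35

    # latent
    n_nuisance: int = 3
    nuisance_sd: float = 0.3
    phase_noise_sd: float = 0.1        # rad
    ring_radius: float = 1.0
    radius_jitter: float = 0.05
    baseline_latent_sd: float = 0.1
    ring_loading_sd: float = 0.15
    nuisance_loading_sd: float = 0.2

    # calcium model
    tau_s: float = 0.6                 # exponential decay of the event kernel
    rate_scale: float = 0.15           # events/frame at zero drive ~ rate_scale*softplus(bias)
    rate_bias: float = 0.2
    noise_sd: float = 0.1
    day_gain_jitter_sd: float = 0.05   # multiplicative across-day stability jitter
    day_drift: float = 0.0             # optional mean-activity drift knob, off by default

    # cohort structure
    presence_p: float = 0.74           # per-day detection probability (0.74^3 ~ 0.405)
    identity_mixing: bool = False      # debug: share loadings exactly across animals

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_p", "frac_baseline_selective", "frac_ts_selective",
                     "frac_struggle_tuned", "frac_immobility_tuned"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.frac_baseline_selective + self.frac_ts_selective > 1:
            raise ParameterError("selectivity fractions must sum to <= 1")
        if self.frac_struggle_tuned + self.frac_immobility_tuned > 1:
            raise ParameterError("movement-tuning fractions must sum to <= 1")
        if self.tau_s <= 0:
            raise ParameterError("tau_s must be positive")
        for f in self.immobility_schedule.values():
            if not 0 <= f <= 1:
                raise ParameterError("immobility fractions must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def immobility_fraction(self, day: int) -> float:
        sched = self.immobility_schedule
        if day in sched:
            return sched[day]
        past = [d for d in sorted(sched) if d <= day]
        if not past:
            raise ParameterError(f"no immobility fraction scheduled at or before day {day}")
        return sched[past[-1]]


@dataclass
class Latent:
    """Per-frame latent state: ring coordinates plus nuisance dimensions."""

    coords: np.ndarray            # (n_frames, 2 + n_nuisance)
    phase: np.ndarray             # rad in [0, 2pi); NaN on baseline frames

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class GroundTruth:
    """Neuron-level generative parameters, shared across days of one animal."""

    loadings: np.ndarray          # (n_neurons, latent dim)
    context_gain: np.ndarray      # multiplicative suspension gain g
    movement_beta: np.ndarray     # coupling to suspension speed
    true_selectivity_class: np.ndarray   # {"baseline", "TS", "none"}
    true_movement_class: np.ndarray      # {"struggle", "immobility", "none"}
    mixing: np.ndarray            # orthogonal animal-mixing matrix
    presence: dict[int, np.ndarray] = field(default_factory=dict)  # day -> bool mask
    latents: dict[int, Latent] = field(default_factory=dict)       # day -> latent
    gain_lo: float = 1 / 1.5
    gain_hi: float = 1.5
    beta_threshold: float = 0.4

    def __post_init__(self) -> None:
        q = self.mixing
        if np.max(np.abs(q.T @ q - np.eye(q.shape[0]))) > 1e-10:
            raise ParameterError("mixing matrix must be orthogonal")

    @property
    def n_neurons(self) -> int:
        return len(self.context_gain)

    def recompute_selectivity_class(self) -> np.ndarray:
        out = np.full(self.n_neurons, "none", dtype=object)
        out[self.context_gain >= self.gain_hi] = "TS"
        out[self.context_gain <= self.gain_lo] = "baseline"
        return out.astype(str)

    def recompute_movement_class(self) -> np.ndarray:
        out = np.full(self.n_neurons, "none", dtype=object)
        out[self.movement_beta >= self.beta_threshold] = "struggle"
        out[self.movement_beta <= -self.beta_threshold] = "immobility"
        return out.astype(str)


# ---------------------------------------------------------------------------
# behavior


def _lognormal_frames(mean_s: float, sigma_log: float, size: int,
                      params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    mu = np.log(mean_s) - sigma_log ** 2 / 2
    dur_s = np.maximum(rng.lognormal(mu, sigma_log, size), params.min_bout_s)
    return np.maximum(np.round(dur_s * params.frame_rate).astype(int), 1)


def _tile_bouts(struggle: np.ndarray, immobility: np.ndarray, n_frames: int) -> np.ndarray:
    """Alternate struggle/immobility bouts, truncated to n_frames."""
    state = np.empty(n_frames, dtype=np.int8)
    t = 0
    for s_dur, i_dur in zip(struggle, immobility):
        for code, dur in ((STRUGGLE, s_dur), (IMMOBILITY, i_dur)):
            if t >= n_frames:
                return state
            end = min(t + dur, n_frames)
            state[t:end] = code
            t = end
    if t < n_frames:  # ran out of bouts; should not happen with enough draws
        state[t:] = STRUGGLE
    return state


def _smooth_noise(n: int, sigma_frames: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d
    noise = rng.standard_normal(n)
    if sigma_frames > 0:
        noise = gaussian_filter1d(noise, sigma_frames, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return noise


def generate_behavior(params: GeneratorParams, day: int,
                      rng: np.random.Generator) -> BehaviorTrack:
    """Baseline segment followed by a bout-structured suspension segment.

    The realized immobility fraction of labeled suspension frames meets the
    day's scheduled target within +-0.05 (bout durations are drawn lognormal,
    then immobility durations are rescaled toward the target).
    """
    target = params.immobility_fraction(day)
    n_ts = params.n_frames_ts
    fr = params.frame_rate

    if target >= 1.0:
        ts_state = np.full(n_ts, IMMOBILITY, dtype=np.int8)
    elif target <= 0.0:
        ts_state = np.full(n_ts, STRUGGLE, dtype=np.int8)
    else:
        imm_mean = params.struggle_bout_mean_s * target / (1 - target)
        n_bouts = max(4, int(np.ceil(2 * n_ts / fr / params.struggle_bout_mean_s)))
        s_dur = _lognormal_frames(params.struggle_bout_mean_s, params.bout_sigma_log,
                                  n_bouts, params, rng)
        i_dur = _lognormal_frames(imm_mean, params.bout_sigma_log, n_bouts, params, rng)
        best, best_err = None, np.inf
        for _ in range(12):
            ts_state = _tile_bouts(s_dur, i_dur, n_ts)
            frac = np.mean(ts_state == IMMOBILITY)
            err = abs(frac - target)
            if err < best_err:
                best, best_err = ts_state, err
            if err <= 0.02:
                break
            # rescale immobility bouts toward the target odds and retile
            realized_odds = frac / max(1 - frac, 1e-9)
            target_odds = target / (1 - target)
            i_dur = np.maximum(np.round(i_dur * target_odds / max(realized_odds, 1e-9)
                                        ).astype(int), 1)
        ts_state = best.copy()
        # final exact correction: move the tail of the longest run of the
        # over-represented state into the other state (keeps bout structure,
        # lands the realized fraction within a frame of the target)
        if best_err > 0.02:
            deficit = int(round(target * n_ts)) - int((ts_state == IMMOBILITY).sum())
            grow, shrink = (IMMOBILITY, STRUGGLE) if deficit > 0 else (STRUGGLE, IMMOBILITY)
            need = abs(deficit)
            min_frames = max(int(params.min_bout_s * fr), 1)
            for _ in range(64):
                if need <= 0:
                    break
                runs = [(e - s, s, e) for s, e, code in _epoch_slices(ts_state)
                        if code == shrink]
                if not runs:
                    break
                length, s, e = max(runs)
                take = min(need, max(length - min_frames, 0))
                if take == 0:
                    break
                ts_state[e - take:e] = grow
                need -= take
        frac = float(np.mean(ts_state == IMMOBILITY))
        if abs(frac - target) > 0.05:
            raise ParameterError(
                f"cannot reach immobility fraction {target} "
                f"(realized {frac:.3f}); bout durations too coarse for the "
                "segment length")

    # coping labels with ambiguous frames at bout transitions
    coping_ts = ts_state.copy()
    k = params.ambiguous_frames_per_transition
    if k > 0:
        trans = np.flatnonzero(np.diff(ts_state) != 0) + 1
        for t in trans:
            coping_ts[t:t + k] = AMBIGUOUS

    n_base = params.n_frames_baseline
    context = np.concatenate([np.zeros(n_base, np.int8), np.ones(n_ts, np.int8)])
    coping = np.concatenate([np.full(n_base, NOT_APPLICABLE, np.int8), coping_ts])

    # speed: mean level per underlying state, slow multiplicative variability
    level = np.empty(n_base + n_ts)
    level[:n_base] = params.speed_baseline
    ts_level = np.where(ts_state == STRUGGLE, params.speed_struggle,
                        params.speed_immobility)
    level[n_base:] = ts_level
    sigma = params.speed_smooth_s * fr
    parts = {}
    for p in range(params.n_speed_parts):
        mod = 1 + params.speed_noise_frac * _smooth_noise(len(level), sigma, rng)
        parts[f"part{p}"] = np.clip(level * mod, 0, None)
    return BehaviorTrack(frame_rate=fr, context=context, coping=coping,
                         speed_parts=parts)


# ---------------------------------------------------------------------------
# latent


def _ts_state_runs(behavior: BehaviorTrack) -> np.ndarray:
    """Suspension-frame coping state with ambiguous frames filled from the
    following bout (ambiguity sits at bout onsets in the generator)."""
    ts_idx = behavior.frames_of_context(TS)
    state = behavior.coping[ts_idx].astype(np.int16)
    amb = state == AMBIGUOUS
    if amb.any():
        filled = state.copy()
        # backward fill: each ambiguous frame takes the next labeled state
        nxt = STRUGGLE
        for i in range(len(filled) - 1, -1, -1):
            if filled[i] == AMBIGUOUS:
                filled[i] = nxt
            else:
                nxt = filled[i]
        state = filled
    return state.astype(np.int8)


def _epoch_slices(state: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, end, code) runs over a 1-d label array."""
    out = []
    edges = np.flatnonzero(np.diff(state) != 0) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(state)]])
    for s, e in zip(starts, ends):
        out.append((int(s), int(e), int(state[s])))
    return out


def generate_latent(behavior: BehaviorTrack, params: GeneratorParams,
                    rng: np.random.Generator) -> Latent:
    """Ring-phase latent over the suspension segment.

    Phase advances monotonically 0 -> pi across each struggle epoch and
    pi -> 2pi across each immobility epoch (one rotation per struggle+
    immobility cycle, consistent direction), with Gaussian phase noise.
    Baseline frames sit near the ring's center.  Nuisance dimensions are
    white noise throughout.
    """
    n = behavior.n_frames
    k = 2 + params.n_nuisance
    coords = np.zeros((n, k))
    phase = np.full(n, np.nan)

    ts_idx = behavior.frames_of_context(TS)
    state = _ts_state_runs(behavior)
    phi = np.empty(len(ts_idx))
    for s, e, code in _epoch_slices(state):
        length = e - s
        half = np.linspace(0.0, np.pi, length, endpoint=False)
        phi[s:e] = half if code == STRUGGLE else half + np.pi
    if params.phase_noise_sd > 0:
        # slow phase jitter: smoothed noise, so the rotation direction of the
        # frame-to-frame trajectory is preserved
        sigma = params.speed_smooth_s * params.frame_rate
        phi = phi + params.phase_noise_sd * _smooth_noise(len(phi), sigma, rng)
    radius = params.ring_radius + rng.normal(0, params.radius_jitter, len(phi))
    coords[ts_idx, 0] = radius * np.cos(phi)
    coords[ts_idx, 1] = radius * np.sin(phi)
    phase[ts_idx] = np.mod(phi, 2 * np.pi)

    base_idx = behavior.frames_of_context(BASELINE)
    coords[base_idx, :2] = rng.normal(0, params.baseline_latent_sd, (len(base_idx), 2))
    coords[:, 2:] = rng.normal(0, params.nuisance_sd, (n, params.n_nuisance))
    return Latent(coords=coords, phase=phase)


# ---------------------------------------------------------------------------
# neurons


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def draw_ground_truth(params: GeneratorParams, rng: np.random.Generator,
                      mixing: np.ndarray | None = None) -> GroundTruth:
    """Draw neuron-level generative parameters (loadings, gains, betas)."""
    n = params.n_neurons
    k = 2 + params.n_nuisance

    loadings = np.column_stack([
        rng.normal(0, params.ring_loading_sd, (n, 2)),
        rng.normal(0, params.nuisance_loading_sd, (n, params.n_nuisance)),
    ])

    # context selectivity: designated fractions get strong gains
    sel = np.full(n, "none", dtype=object)
    n_b = int(round(params.frac_baseline_selective * n))
    n_t = int(round(params.frac_ts_selective * n))
    order = rng.permutation(n)
    sel[order[:n_b]] = "baseline"
    sel[order[n_b:n_b + n_t]] = "TS"
    log_g = rng.normal(0, params.gain_null_log_sd, n)
    strong = np.log(params.gain_strength)
    log_g[sel == "TS"] = rng.normal(strong, params.gain_log_sd, int((sel == "TS").sum()))
    log_g[sel == "baseline"] = rng.normal(-strong, params.gain_log_sd,
                                          int((sel == "baseline").sum()))
    gain = np.exp(log_g)

    # movement tuning: continuous betas, tuned fractions at the extremes
    mov = np.full(n, "none", dtype=object)
    n_s = int(round(params.frac_struggle_tuned * n))
    n_i = int(round(params.frac_immobility_tuned * n))
    order = rng.permutation(n)
    mov[order[:n_s]] = "struggle"
    mov[order[n_s:n_s + n_i]] = "immobility"
    beta = rng.normal(0, params.beta_null_sd, n)
    beta[mov == "struggle"] = np.abs(
        rng.normal(params.beta_tuned_mean, params.beta_tuned_sd, int((mov == "struggle").sum())))
    beta[mov == "immobility"] = -np.abs(
        rng.normal(params.beta_tuned_mean, params.beta_tuned_sd, int((mov == "immobility").sum())))

    if mixing is None:
        mixing = np.eye(k)
    truth = GroundTruth(loadings=loadings, context_gain=gain, movement_beta=beta,
                        true_selectivity_class=sel.astype(str),
                        true_movement_class=mov.astype(str), mixing=mixing)
    # class labels must be recomputable from the drawn parameters
    truth.true_selectivity_class = truth.recompute_selectivity_class()
    truth.true_movement_class = truth.recompute_movement_class()
    return truth


def generate_session(params: GeneratorParams, day: int,
                     truth: GroundTruth | None,
                     rng: np.random.Generator,
                     animal_id: str = "sim0",
                     neuron_subset: np.ndarray | None = None,
                     neuron_ids: np.ndarray | None = None,
                     ) -> tuple[SessionRecording, GroundTruth]:
    """Simulate one animal-day.

    Per-neuron instantaneous rate is
    ``rate_scale * softplus(loadings . latent + beta * speed_norm_TS + bias)
    * gain^[context == TS]``; Poisson events are convolved with an
    exponential kernel, Gaussian noise is added, traces are z-scored and
    transients recomputed with the standard preprocessing rule.
    """
    rng_beh, rng_lat, rng_cal = rng.spawn(3)
    behavior = generate_behavior(params, day, rng_beh)
    latent = generate_latent(behavior, params, rng_lat)
    if truth is None:
        truth = draw_ground_truth(params, rng_cal.spawn(1)[0])
    truth.latents[day] = latent

    loadings = truth.loadings @ truth.mixing
    gain = truth.context_gain
    beta = truth.movement_beta
    if neuron_subset is not None:
        loadings = loadings[neuron_subset]
        gain = gain[neuron_subset]
        beta = beta[neuron_subset]

    is_ts = (behavior.context == TS).astype(float)
    speed_norm = behavior.speed_mean / params.speed_struggle * is_ts
    drive = loadings @ latent.coords.T + beta[:, None] * speed_norm[None, :] \
        + params.rate_bias
    rate = params.rate_scale * _softplus(drive)
    rate = rate * np.power(gain[:, None], is_ts[None, :])
    if params.day_gain_jitter_sd > 0 and neuron_subset is not None:
        jitter = rng_cal.lognormal(0, params.day_gain_jitter_sd, rate.shape[0])
        rate = rate * jitter[:, None]
    if params.day_drift != 0:
        rate = rate * np.exp(params.day_drift * (day - 1))

    events = rng_cal.poisson(rate).astype(np.float64)
    rho = np.exp(-1.0 / (params.tau_s * params.frame_rate))
    traces = lfilter([1.0], [1.0, -rho], events, axis=1)
    if params.noise_sd > 0:
        traces = traces + rng_cal.normal(0, params.noise_sd, traces.shape)
    z = zscore(traces)
    transients = detect_transients(z, k=2.0)
    if neuron_ids is None:
        neuron_ids = np.arange(z.shape[0], dtype=np.int64)
    calcium = CalciumTraces(values=z, neuron_ids=neuron_ids,
                            transients=transients, frame_rate=params.frame_rate)
    session = SessionRecording(animal_id=animal_id, day=day, calcium=calcium,
                               behavior=behavior)
    return session, truth


def generate_multiday(params: GeneratorParams, days: list[int],
                      rng: np.random.Generator, animal_id: str = "sim0",
                      truth: GroundTruth | None = None,
                      ) -> tuple[list[SessionRecording], RegistrationMap, GroundTruth]:
    """Simulate one animal over several days with partial cell overlap.

    One shared ground truth; each neuron is independently present on each day
    with probability ``presence_p``; the registration table reflects presence
    exactly (local row index, or -1 when absent).
    """
    if len(days) < 2:
        raise ParameterError("need at least 2 days")
    rng_truth, rng_pres, *day_rngs = rng.spawn(2 + len(days))
    if truth is None:
        truth = draw_ground_truth(params, rng_truth)
    n = truth.n_neurons
    for day in days:
        while True:
            mask = rng_pres.random(n) < params.presence_p
            if mask.any():
                break
        truth.presence[day] = mask

    sessions = []
    table = pd.DataFrame(-1, index=pd.Index(np.arange(n), name="global_id"),
                         columns=[f"day{d}" for d in days], dtype=np.int64)
    for day, drng in zip(days, day_rngs):
        present = np.flatnonzero(truth.presence[day])
        sess, _ = generate_session(params, day, truth, drng, animal_id=animal_id,
                                   neuron_subset=present,
                                   neuron_ids=np.arange(len(present), dtype=np.int64))
        sessions.append(sess)
        table.loc[present, f"day{day}"] = np.arange(len(present))
    return sessions, RegistrationMap(table), truth


def generate_cohort(params: GeneratorParams, n_animals: int,
                    rng: np.random.Generator, days: list[int] | None = None,
                    ) -> list[tuple[list[SessionRecording], RegistrationMap, GroundTruth]]:
    """Simulate several animals sharing one latent behavior-to-phase law.

    All animals reuse one set of base neuron parameters whose loadings are
    passed through an independent Haar-random orthogonal mixing matrix per
    animal; behavior realizations are independent.
    """
    if n_animals < 2:
        raise ParameterError("need at least 2 animals")
    days = days or [1, 3]
    k = 2 + params.n_nuisance
    rng_truth, rng_mix, *animal_rngs = rng.spawn(2 + n_animals)
    base = draw_ground_truth(params, rng_truth)
    out = []
    for a, arng in enumerate(animal_rngs):
        if params.identity_mixing:
            mixing = np.eye(k)
        else:
            mixing = special_ortho_group.rvs(k, random_state=rng_mix)
        truth = GroundTruth(loadings=base.loadings.copy(),
                            context_gain=base.context_gain.copy(),
                            movement_beta=base.movement_beta.copy(),
                            true_selectivity_class=base.true_selectivity_class.copy(),
                            true_movement_class=base.true_movement_class.copy(),
                            mixing=mixing)
        sessions, regmap, truth = generate_multiday(params, days, arng,
                                                    animal_id=f"sim{a}", truth=truth)
        out.append((sessions, regmap, truth))
    return out
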