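"""End-to-end study analog: simulate (or load), score, decode, align, report.

``run_study`` drives the full pipeline on a multi-animal, multi-day cohort
and emits a JSON-serializable report with per-animal, per-day entries:
behavior summaries, neuron counts and repeated-identification fractions,
selectivity distributions and their across-day correlations, movement-score
summaries, within/cross-condition speed decoding, across-day decoding via
registered neurons and via aligned manifolds, and cross-animal alignment
scores -- each decoding entry with its surrogate or null comparator.

Group-level hypothesis testing is intentionally not performed here; the
report exposes raw per-animal metrics so any statistics package can be
applied downstream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import AnalysisConfig, child_rng
from .decoding import (DecodingResult, across_day_decode, decode_coping,
                       decode_context, speed_condition_matrix)
from .manifold import (align_manifolds, center_scale_manifold, circular_pairing,
                       cross_manifold_decode, embed, shuffle_null_embedding)
from .preprocess import smooth_quantile_scale
from .session import (IMMOBILITY, STRUGGLE, TS, RegistrationMap,
                      SessionRecording, repeatedly_identified)
from .synthetic import GeneratorParams, generate_cohort
from .tuning import score_session, selectivity_day_correlation

logger = logging.getLogger("copingmanifold")


def compare_to_null(real: DecodingResult, null: DecodingResult | np.ndarray) -> dict:
    """Effect-size record: real mean, null mean, difference, and the real
    score's percentile within the null distribution.

    When both arguments are DecodingResults their fold-index hashes must
    match (paired comparisons share fold templates by design).
    """
    if isinstance(null, DecodingResult):
        if real.fold_hash and null.fold_hash and real.fold_hash != null.fold_hash:
            raise ValueError("fold index templates differ between real and null")
        null_scores = null.fold_scores
    else:
        null_scores = np.asarray(null, dtype=np.float64)
    real_mean = real.mean_score
    null_mean = float(np.mean(null_scores))
    pct = float(100.0 * np.mean(null_scores <= real_mean)) if len(null_scores) else np.nan
    return dict(real_mean=real_mean, null_mean=null_mean,
                difference=real_mean - null_mean, percentile=pct,
                n_null=int(len(null_scores)))


def _behavior_summary(session: SessionRecording) -> dict:
    beh = session.behavior
    fr = beh.frame_rate
    ts = beh.frames_of_context(TS)
    strug = beh.frames_of_coping(STRUGGLE)
    immo = beh.frames_of_coping(IMMOBILITY)
    return dict(
        immobility_time_s=len(immo) / fr,
        struggle_time_s=len(strug) / fr,
        immobility_fraction=len(immo) / max(len(strug) + len(immo), 1),
        mean_speed_ts=float(beh.speed_mean[ts].mean()),
    )


def _selectivity_summary(table, threshold: float) -> dict:
    s = table["ts_selectivity_raw"].to_numpy()
    ok = np.isfinite(s)
    return dict(
        median_raw=float(np.median(s[ok])),
        prop_baseline_selective=float(np.mean(s[ok] < -threshold)),
        prop_ts_selective=float(np.mean(s[ok] > threshold)),
        n=int(ok.sum()),
    )


def _movement_summary(table) -> dict:
    b = table["movement_score_baseline"].to_numpy()
    t = table["movement_score_TS"].to_numpy()
    ok = np.isfinite(b) & np.isfinite(t)
    return dict(
        mean_abs_baseline=float(np.mean(np.abs(b[ok]))),
        mean_abs_ts=float(np.mean(np.abs(t[ok]))),
        prop_struggle_tuned=float(np.mean(t[ok] > 0.2)),
        prop_immobility_tuned=float(np.mean(t[ok] < -0.2)),
    )


def _manifold_coords(session: SessionRecording, config: AnalysisConfig,
                     rng: np.random.Generator, shuffle: bool = False):
    """Scaled-trace embedding of the suspension segment plus coping labels."""
    ts = session.behavior.frames_of_context(TS)
    scaled = smooth_quantile_scale(session.calcium.values[:, ts],
                                   session.behavior.frame_rate,
                                   config.smooth_sigma_s, config.n_quantiles)
    n_neighbors = min(config.isomap_neighbors, len(ts) // 4)
    if shuffle:
        emb = shuffle_null_embedding(scaled, rng, method=config.embedding_method,
                                     d=config.embedding_dims, n_neighbors=n_neighbors,
                                     fit_fraction=config.fit_fraction, frames=ts, rng=rng)
    else:
        emb = embed(scaled, method=config.embedding_method, d=config.embedding_dims,
                    n_neighbors=n_neighbors, fit_fraction=config.fit_fraction,
                    frames=ts, rng=rng)
    coping = session.behavior.coping[ts]
    labels = np.where(coping == STRUGGLE, 1, np.where(coping == IMMOBILITY, 0, -1))
    return emb, coping, labels


def _aligned_cross_decode(ref, tgt, config, rng, rotation_reps):
    """Align target onto reference and decode coping across manifolds."""
    (emb_r, coping_r, y_r), (emb_t, coping_t, y_t) = ref, tgt
    res = align_manifolds(emb_t.coords, coping_t, emb_r.coords, coping_r,
                          config.template_digits)
    ref_coords = center_scale_manifold(emb_r.coords)
    keep_r, keep_t = y_r >= 0, y_t >= 0
    return res, cross_manifold_decode(ref_coords[keep_r], y_r[keep_r],
                                      res.aligned[keep_t], y_t[keep_t],
                                      task="coping", config=config,
                                      rotation_reps=rotation_reps, rng=rng)


def run_study(config: AnalysisConfig | None = None,
              params: GeneratorParams | None = None,
              n_animals: int = 4, days: list[int] | None = None,
              out_dir: str | Path | None = None) -> dict:
    """Run the full study analog on a synthetic cohort and return the report.

    Deterministic given ``config.seed``; when ``out_dir`` is given the report
    is also written as ``report.json`` next to the resolved config.
    """
    config = config or AnalysisConfig()
    params = params or GeneratorParams()
    days = days or [1, 3, 9]
    config.log_resolved()
    master = config.seed

    cohort = generate_cohort(params, n_animals, child_rng(master, "cohort"), days=days)
    report: dict = {"seed": master, "n_animals": n_animals, "days": days,
                    "config": config.to_dict(), "generator": params.to_dict(),
                    "animals": {}}

    embeddings: dict[tuple[str, int], tuple] = {}
    for a, (sessions, regmap, truth) in enumerate(cohort):
        animal = sessions[0].animal_id
        logger.info("analyzing animal %s", animal)
        arec: dict = {"days": {}, "across_days": {}}
        tables = {}
        for sess in sessions:
            rng_d = child_rng(master, "animal", a, "day", sess.day)
            table = score_session(sess, config)
            tables[sess.day] = table
            coping = decode_coping(sess, config=config,
                                   n_surrogates=config.decode_surrogates, rng=rng_d)
            context = decode_context(sess, config=config,
                                     n_surrogates=config.decode_surrogates, rng=rng_d)
            speed = speed_condition_matrix(sess, config=config,
                                           n_surrogates=config.decode_surrogates,
                                           rng=rng_d)
            arec["days"][sess.day] = dict(
                behavior=_behavior_summary(sess),
                n_neurons=sess.calcium.n_neurons,
                selectivity=_selectivity_summary(table, config.selectivity_threshold),
                movement=_movement_summary(table),
                coping_decoding=compare_to_null(coping, coping.surrogate_scores),
                context_decoding=compare_to_null(context, context.surrogate_scores),
                speed_decoding={f"{tr}->{te}": r.to_dict()
                                for (tr, te), r in speed.items()},
            )

        # across-day structure
        ids = repeatedly_identified(regmap, days)
        arec["repeated_fraction"] = len(ids) / truth.n_neurons
        arec["selectivity_day_correlation"] = {
            f"{days[0]}-{d}": selectivity_day_correlation(tables, regmap, days[0], d)
            for d in days[1:]}
        arec["movement_day_correlation"] = {
            f"{days[0]}-{d}": selectivity_day_correlation(
                tables, regmap, days[0], d, column="movement_score_TS")
            for d in days[1:]}
        rng_x = child_rng(master, "animal", a, "acrossday")
        across = across_day_decode(sessions, regmap, task="coping", config=config,
                                   n_surrogates=config.decode_surrogates, rng=rng_x)
        arec["across_days"]["coping_registered"] = {
            d: compare_to_null(r, r.surrogate_scores) for d, r in across.items()}

        # manifold path: day-1 reference vs later days, aligned
        rng_m = child_rng(master, "animal", a, "manifold")
        for sess in sessions:
            embeddings[(animal, sess.day)] = _manifold_coords(sess, config, rng_m)
        aligned_rec = {}
        for d in days[1:]:
            _, scores = _aligned_cross_decode(embeddings[(animal, days[0])],
                                              embeddings[(animal, d)],
                                              config, rng_m, config.rotation_reps)
            aligned_rec[d] = dict(
                aligned=compare_to_null(scores["target"], scores["rotation"]),
                within=scores["within"].mean_score)
        arec["across_days"]["coping_aligned"] = aligned_rec
        report["animals"][animal] = arec

    # cross-animal alignment on day 1, circular pairing
    animal_names = [c[0][0].animal_id for c in cohort]
    rng_c = child_rng(master, "crossanimal")
    pairs = circular_pairing(animal_names)
    xrec = {}
    for ref_name, tgt_name in pairs:
        _, scores = _aligned_cross_decode(embeddings[(ref_name, days[0])],
                                          embeddings[(tgt_name, days[0])],
                                          config, rng_c, config.rotation_reps)
        xrec[f"{ref_name}->{tgt_name}"] = dict(
            aligned=compare_to_null(scores["target"], scores["rotation"]),
            within=scores["within"].mean_score)
    report["cross_animal"] = xrec

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.save(out_dir / "config.yaml")
    return report
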