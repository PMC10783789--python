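"""Low-dimensional manifolds: embedding, trajectories, and alignment.

Population activity during suspension traverses a roughly circular
low-dimensional trajectory spanning struggle and immobility.  This module

* embeds smoothed, quantile-scaled traces into d dimensions (isomap by
  default, fit on an evenly strided 60% frame subset; PCA and spectral
  embedding as alternatives);
* characterizes rotational structure on a 2-d plane: flow fields (15 x 15
  binned mean velocity vectors) and turn-angle series (consecutive velocity
  angle differences mod 2pi; angles in (0, pi) are leftward turns);
* builds "template manifolds": each coping epoch is rescaled to a fixed
  number of progression digits (default 20) and averaged per digit and
  dimension, giving a d x 2*n_digits matrix (struggle digits then
  immobility digits);
* solves the orthogonal Procrustes problem between two centered, unit-norm
  templates -- Q = U V^T from the SVD of A^T B minimizes ||AQ - B||_F over
  orthogonal Q -- and applies Q to the full manifold;
* provides the two alignment nulls of the analysis: Haar-random rotations
  (det +1) of the aligned manifold, and re-embedding of circularly shifted
  traces ("shuffle"), plus cross-manifold decoding between a reference
  manifold and an aligned target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import special_ortho_group
from sklearn.decomposition import PCA
from sklearn.manifold import Isomap, SpectralEmbedding

from .config import AnalysisConfig
from .decoding import (DecodingResult, balance_binary, circular_shift_surrogate,
                       cross_condition_decode, fold_indices)
from .preprocess import ScaledTraces
from .session import IMMOBILITY, STRUGGLE


@dataclass
class ManifoldEmbedding:
    """Latent coordinates (frames x d) plus provenance."""

    coords: np.ndarray
    method: str
    n_neighbors: int | None = None
    fit_fraction: float | None = None
    frames: np.ndarray | None = None   # indices into the source session

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")
        if self.coords.shape[1] < 2:
            raise ValueError("need at least 2 embedding dimensions")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class TemplateManifold:
    """Epoch-averaged trajectory: d x (2 * n_digits), struggle then immobility."""

    matrix: np.ndarray
    n_digits: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != 2 * self.n_digits:
            raise ValueError("template must have 2 * n_digits columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("template has empty digits (NaN columns)")

    @property
    def as_time_by_dim(self) -> np.ndarray:
        """Transposed view (2*n_digits x d) used by the Procrustes solver."""
        return self.matrix.T


@dataclass
class AlignmentResult:
    """Orthogonal transform aligning a target manifold to a reference."""

    Q: np.ndarray
    residual: float               # ||A Q - B||_F on the templates
    identity_residual: float      # ||A - B||_F, for the never-worse check
    aligned: np.ndarray | None = None   # M Q for the full target manifold
    degenerate: bool = False      # rank-deficient A^T B: Q non-unique

    def __post_init__(self) -> None:
        q = self.Q
        if np.max(np.abs(q.T @ q - np.eye(q.shape[0]))) > 1e-8:
            raise ValueError("Q must be orthogonal")


@dataclass
class FlowField:
    """Binned mean velocity vectors on a 2-d manifold plane.

    Velocities are consecutive-frame differences assigned to the bin of the
    segment midpoint; per-bin mean positions are kept so tangency/rotation
    statistics can be computed against the local radius.
    """

    mean_velocity: np.ndarray     # (bins, bins, 2); NaN where empty
    mean_position: np.ndarray     # (bins, bins, 2); NaN where empty
    occupancy: np.ndarray         # (bins, bins) int counts
    edges_x: np.ndarray
    edges_y: np.ndarray


# ---------------------------------------------------------------------------
# embedding


def embed(scaled: ScaledTraces | np.ndarray, method: str = "isomap",
          d: int = 5, n_neighbors: int = 500, fit_fraction: float = 0.6,
          frames: np.ndarray | None = None,
          rng: np.random.Generator | None = None) -> ManifoldEmbedding:
    """Embed scaled traces (neurons x frames) into d dimensions.

    Isomap is fit on an evenly strided ``fit_fraction`` subset of frames and
    then transforms all frames; PCA and spectral embedding fit on the full
    data.  The Euclidean metric is used throughout.
    """
    values = scaled.values if isinstance(scaled, ScaledTraces) else np.asarray(scaled)
    X = values.T  # frames x neurons
    n = X.shape[0]
    if method == "isomap":
        if n <= n_neighbors:
            raise ValueError(f"need more than n_neighbors={n_neighbors} frames, got {n}")
        n_fit = max(int(round(n * fit_fraction)), n_neighbors + 1)
        fit_idx = np.unique(np.linspace(0, n - 1, n_fit).round().astype(int))
        model = Isomap(n_neighbors=n_neighbors, n_components=d, metric="euclidean")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X[fit_idx])
                coords = model.transform(X)
            except Exception as e:  # disconnected neighborhood graph etc.
                raise ValueError(
                    f"isomap failed ({e}); try a larger n_neighbors") from e
    elif method == "pca":
        coords = PCA(n_components=d).fit(X).transform(X)
    elif method == "spectral":
        seed = None if rng is None else int(rng.integers(2 ** 31))
        model = SpectralEmbedding(n_components=d, n_neighbors=n_neighbors,
                                  random_state=seed)
        coords = model.fit_transform(X)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ManifoldEmbedding(coords=coords, method=method, n_neighbors=n_neighbors,
                             fit_fraction=fit_fraction if method == "isomap" else None,
                             frames=frames)


# ---------------------------------------------------------------------------
# trajectory statistics


def _time_bin(coords: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean-bin frames into n_bins consecutive temporal chunks."""
    n = coords.shape[0]
    bounds = np.linspace(0, n, n_bins + 1).astype(int)
    return np.array([coords[a:b].mean(axis=0) for a, b in zip(bounds[:-1], bounds[1:])
                     if b > a])


def turn_angles(plane: np.ndarray, frame_rate: float = 20.0,
                target_rate_hz: float = 2.67, n_bins: int | None = None,
                ) -> tuple[np.ndarray, float, int]:
    """Turn-angle series of a 2-d trajectory and its leftward fraction.

    The trajectory is mean-binned to ``target_rate_hz`` (or an explicit bin
    count), velocity angles are taken with the two-argument arctangent, and
    consecutive differences are reduced mod 2pi.  Angles in (0, pi) are
    leftward (counterclockwise) turns.  Returns (angles, leftward fraction,
    number of zero-velocity steps skipped).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if n_bins is None:
        n_bins = max(int(round(plane.shape[0] / frame_rate * target_rate_hz)), 3)
    binned = _time_bin(plane, n_bins)
    if binned.shape[0] < 3:
        raise ValueError("need at least 3 time bins")
    v = np.diff(binned, axis=0)
    speed = np.linalg.norm(v, axis=1)
    keep = speed > 0
    skipped = int((~keep).sum())
    theta = np.arctan2(v[keep, 1], v[keep, 0])
    angles = np.mod(np.diff(theta), 2 * np.pi)
    leftward = float(np.mean((angles > 0) & (angles < np.pi))) if len(angles) else np.nan
    return angles, leftward, skipped


def plane_rotation_criterion(plane: np.ndarray, frame_rate: float = 20.0,
                             target_rate_hz: float = 2.67) -> float:
    """Winding coherence of a 2-d trajectory, in [0, 1].

    The time-binned trajectory is centered on its centroid; signed increments
    of the position angle are summed.  The score is |net winding| / total
    |winding|, damped when less than one full revolution is traversed.  A
    consistent rotation scores 1, an isotropic random walk ~ 1/sqrt(n_steps),
    a straight line 0.  (Velocity turn angles are too fragile here: the
    anti-correlation of consecutive noise velocities piles turn angles up
    near +-pi and outscores genuine slow rotation.)
    """
    plane = np.asarray(plane, dtype=np.float64)
    n_bins = max(int(round(plane.shape[0] / frame_rate * target_rate_hz)), 3)
    binned = _time_bin(plane, n_bins)
    centered = binned - binned.mean(axis=0)
    theta = np.arctan2(centered[:, 1], centered[:, 0])
    d = np.angle(np.exp(1j * np.diff(theta)))    # signed, (-pi, pi]
    total = np.abs(d).sum()
    if total == 0:
        return 0.0
    coherence = abs(d.sum()) / total * min(1.0, total / (2 * np.pi))
    # a rotation keeps a near-constant radius; a diametric oscillation (which
    # also winds, through near-origin passes) does not
    radius = np.linalg.norm(centered, axis=1)
    uniformity = max(0.0, 1.0 - radius.std() / radius.mean()) if radius.mean() > 0 else 0.0
    return float(coherence * uniformity)


def select_plane(embedding: ManifoldEmbedding | np.ndarray,
                 frame_rate: float = 20.0, target_rate_hz: float = 2.67,
                 ) -> tuple[int, int]:
    """Axis pair carrying the strongest consistent rotation.

    Pairs are ranked by :func:`plane_rotation_criterion`; ties break to the
    lowest axis indices.  This automates the visual plane selection of the
    original analysis.
    """
    coords = embedding.coords if isinstance(embedding, ManifoldEmbedding) else embedding
    d = coords.shape[1]
    best, best_score = (0, 1), -np.inf
    for i in range(d):
        for j in range(i + 1, d):
            score = plane_rotation_criterion(coords[:, [i, j]], frame_rate,
                                             target_rate_hz)
            if score > best_score + 1e-12:
                best, best_score = (i, j), score
    return best


def flow_field(plane: np.ndarray, bins: int = 15) -> FlowField:
    """Spatially binned mean velocity vectors over a 2-d plane.

    Each consecutive-frame velocity is assigned to the bin containing the
    segment midpoint; the grid covers the bounding box of the data.
    Occupancy sums to n_frames - 1.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    v = np.diff(plane, axis=0)
    mid = 0.5 * (plane[:-1] + plane[1:])
    edges_x = np.linspace(plane[:, 0].min(), plane[:, 0].max(), bins + 1)
    edges_y = np.linspace(plane[:, 1].min(), plane[:, 1].max(), bins + 1)
    ix = np.clip(np.searchsorted(edges_x, mid[:, 0], side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(edges_y, mid[:, 1], side="right") - 1, 0, bins - 1)
    occupancy = np.zeros((bins, bins), dtype=int)
    sums_v = np.zeros((bins, bins, 2))
    sums_p = np.zeros((bins, bins, 2))
    np.add.at(occupancy, (ix, iy), 1)
    np.add.at(sums_v, (ix, iy), v)
    np.add.at(sums_p, (ix, iy), mid)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_v = sums_v / occupancy[..., None]
        mean_p = sums_p / occupancy[..., None]
    return FlowField(mean_velocity=mean_v, mean_position=mean_p,
                     occupancy=occupancy, edges_x=edges_x, edges_y=edges_y)


# ---------------------------------------------------------------------------
# alignment


def center_scale_manifold(coords: np.ndarray) -> np.ndarray:
    """Shift the centroid to the origin and scale to unit Frobenius norm."""
    coords = np.asarray(coords, dtype=np.float64)
    centered = coords - coords.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(centered)
    if norm == 0:
        raise ValueError("all frames identical; manifold has no extent")
    return centered / norm


def epoch_digits(labels: np.ndarray, code: int, n_digits: int,
                 min_frames: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of all epochs of ``code`` and their progression digits.

    Each contiguous run of ``code`` is mapped to digits 1..n_digits evenly
    spaced start -> end (rounded; short epochs reuse digits, epochs shorter
    than ``min_frames`` are excluded).
    """
    labels = np.asarray(labels)
    mask = labels == code
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = list(edges[mask[edges + 1]] + 1) if len(edges) else []
    if mask[0]:
        starts = [0] + starts
    frames, digits = [], []
    for s in starts:
        e = s
        while e < len(labels) and labels[e] == code:
            e += 1
        length = e - s
        if length < min_frames:
            continue
        pos = np.round(np.linspace(1, n_digits, length)).astype(int)
        frames.append(np.arange(s, e))
        digits.append(pos)
    if not frames:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(frames), np.concatenate(digits)


def build_template(coords: np.ndarray, coping: np.ndarray,
                   n_digits: int = 20) -> TemplateManifold:
    """Average struggle and immobility epochs into a d x 2*n_digits template.

    Frames of every epoch are assigned progression digits 1..n_digits and
    averaged per digit and dimension over all epochs of that coping class
    (per-frame mean within digit); struggle columns precede immobility
    columns.  With the defaults and d = 5 the template is exactly 5 x 40.
    """
    coords = np.asarray(coords, dtype=np.float64)
    d = coords.shape[1]
    cols = []
    for code, name in ((STRUGGLE, "struggle"), (IMMOBILITY, "immobility")):
        frames, digits = epoch_digits(np.asarray(coping), code, n_digits)
        if len(frames) == 0:
            raise ValueError(f"no complete {name} epoch")
        block = np.full((d, n_digits), np.nan)
        for g in range(1, n_digits + 1):
            sel = frames[digits == g]
            if len(sel) == 0:
                raise ValueError(f"{name} digit {g} received no frames")
            block[:, g - 1] = coords[sel].mean(axis=0)
        cols.append(block)
    return TemplateManifold(matrix=np.concatenate(cols, axis=1), n_digits=n_digits)


def procrustes_align(template_a: TemplateManifold | np.ndarray,
                     template_b: TemplateManifold | np.ndarray) -> AlignmentResult:
    """Orthogonal Procrustes: Q minimizing ||A Q - B||_F.

    A and B are time-by-dimension matrices (templates are transposed from
    their stored d x 2*n_digits orientation).  With A^T B = U S V^T and
    singular values in decreasing order, Q = U V^T is the global optimum
    over all orthogonal matrices (possibly a reflection).  Rank deficiency
    of A^T B makes the optimum non-unique and is flagged.
    """
    A = template_a.as_time_by_dim if isinstance(template_a, TemplateManifold) \
        else np.asarray(template_a, dtype=np.float64)
    B = template_b.as_time_by_dim if isinstance(template_b, TemplateManifold) \
        else np.asarray(template_b, dtype=np.float64)
    if A.shape != B.shape:
        raise ValueError("templates must have the same shape")
    M = A.T @ B
    U, s, Vt = np.linalg.svd(M)
    Q = U @ Vt
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if len(s) else 0)
    degenerate = bool(np.sum(s > tol) < len(s))
    residual = float(np.linalg.norm(A @ Q - B))
    identity_residual = float(np.linalg.norm(A - B))
    return AlignmentResult(Q=Q, residual=residual,
                           identity_residual=identity_residual,
                           degenerate=degenerate)


def apply_alignment(manifold: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotate a full (centered, scaled) manifold: M -> M Q."""
    manifold = np.asarray(manifold, dtype=np.float64)
    if manifold.shape[1] != Q.shape[0]:
        raise ValueError("manifold and Q dimensions differ")
    return manifold @ Q


def align_manifolds(target_coords: np.ndarray, target_coping: np.ndarray,
                    reference_coords: np.ndarray, reference_coping: np.ndarray,
                    n_digits: int = 20) -> AlignmentResult:
    """Full path: center/scale both manifolds, build templates, align target
    onto the reference, and attach the rotated full target manifold."""
    tgt = center_scale_manifold(target_coords)
    ref = center_scale_manifold(reference_coords)
    res = procrustes_align(build_template(tgt, target_coping, n_digits),
                           build_template(ref, reference_coping, n_digits))
    res.aligned = apply_alignment(tgt, res.Q)
    return res


def haar_rotations(d: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """``reps`` Haar-uniform special-orthogonal matrices (det +1)."""
    mats = special_ortho_group.rvs(d, size=reps, random_state=rng)
    return mats if reps > 1 else mats[None, ...]


def shuffle_null_embedding(scaled: ScaledTraces, rng: np.random.Generator,
                           **embed_kw) -> ManifoldEmbedding:
    """Shuffle-null manifold: circularly shift each neuron's scaled trace,
    then re-embed.  Per-neuron marginals are preserved exactly."""
    shifted = circular_shift_surrogate(scaled.values, rng)
    return embed(shifted, **embed_kw)


# ---------------------------------------------------------------------------
# cross-manifold decoding


def _balanced_pair_indices(y_ref: np.ndarray, y_tgt: np.ndarray,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Equal class counts within and between two labeled frame sets."""
    m = int(min((y_ref == 0).sum(), (y_ref == 1).sum(),
                (y_tgt == 0).sum(), (y_tgt == 1).sum()))
    if m == 0:
        raise ValueError("a coping class is absent in one dataset")

    def pick(y: np.ndarray) -> np.ndarray:
        keep = [rng.choice(np.flatnonzero(y == c), size=m, replace=False)
                for c in (0, 1)]
        return np.sort(np.concatenate(keep))

    return pick(y_ref), pick(y_tgt)


def cross_manifold_decode(reference_coords: np.ndarray, reference_labels: np.ndarray,
                          target_coords: np.ndarray, target_labels: np.ndarray,
                          task: str = "coping",
                          config: AnalysisConfig | None = None,
                          rotation_reps: int = 0,
                          rng: np.random.Generator | None = None,
                          ) -> dict[str, DecodingResult | np.ndarray]:
    """Train on the reference manifold, predict behavior on the target.

    For the binary task the two datasets are balanced to equal struggle and
    immobility counts within and between them; one fold-index template is
    shared by the within-reference score, the target score, and every
    random-rotation variant.  Returns ``{"target", "within", "rotation"}``
    (rotation scores only when ``rotation_reps > 0``).
    """
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.seed)
    if task == "coping":
        i_ref, i_tgt = _balanced_pair_indices(reference_labels, target_labels, rng)
        Xr, yr = reference_coords[i_ref], reference_labels[i_ref]
        Xt, yt = target_coords[i_tgt], target_labels[i_tgt]
        model = "logistic"
    elif task == "speed":
        n = min(len(reference_labels), len(target_labels))
        Xr, yr = reference_coords[:n], reference_labels[:n]
        Xt, yt = target_coords[:n], target_labels[:n]
        model = "ridge"
    else:
        raise ValueError(f"unknown task {task!r}")
    folds_ix = fold_indices(Xr.shape[0], config.folds, config.contiguous_folds, rng)
    out: dict[str, DecodingResult | np.ndarray] = {
        "target": cross_condition_decode(Xr, yr, Xt, yt, task=task, model=model,
                                         config=config, folds_ix=folds_ix,
                                         train_condition="reference",
                                         test_condition="target"),
        "within": cross_condition_decode(Xr, yr, Xr, yr, task=task, model=model,
                                         config=config, folds_ix=folds_ix,
                                         train_condition="reference",
                                         test_condition="reference"),
    }
    if rotation_reps > 0:
        rots = haar_rotations(Xt.shape[1], rotation_reps, rng)
        scores = []
        for R in rots:
            r = cross_condition_decode(Xr, yr, Xt @ R, yt, task=task, model=model,
                                       config=config, folds_ix=folds_ix)
            scores.append(r.mean_score)
        out["rotation"] = np.array(scores)
    return out


def circular_pairing(animals: list) -> list[tuple]:
    """Reference -> target pairs around the animal list: (a_{n-1} -> a_n),
    wrapping so the first animal's reference is the last animal."""
    if len(animals) < 2:
        raise ValueError("need at least 2 animals")
    return [(animals[i - 1], animals[i]) for i in range(len(animals))]
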