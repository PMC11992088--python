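"""Inter-session alignment: vessel-similarity scoring, multiscale pairwise
registration, weighted groupwise atlas construction, and orchestration with
an automatic neuron-only fallback.

The coarse-to-fine schedule registers vessel projections first (their
intricate shapes avoid the local minima that homogeneous neuron blobs fall
into) and refines on neuron projections at full resolution. With more than
two sessions, every ordered pair is registered and each session is mapped
into a common atlas that minimizes weighted displacement across sessions:

    T_(s->CA) = -(1/N) * sum_i T_(i->s) . W_s

where W_s is a per-pixel weight map reflecting session s's post-alignment
local vessel similarity to the other sessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity
from skimage.transform import resize

from .config import DemonsConfig, VesselFilterConfig
from .demons import (RegistrationDivergence, compose_fields, is_diffeomorphic,
                     log_demons_register, warp)
from .preprocess import detrend_and_scale
from .projections import ProjectionImage, crispness
from .simulate import gradient_gaussian_field
from .vessels import VesselImage, enhance_vessels

__all__ = [
    "SessionSummary",
    "BVScore",
    "AtlasSolution",
    "build_session_summary",
    "bv_similarity_score",
    "multiscale_align_pair",
    "local_similarity_weights",
    "groupwise_atlas",
    "align_sessions",
]

log = logging.getLogger(__name__)

BV_THRESHOLD_DEFAULT = 2.7

# pyramid schedule: image scale and channel per level (coarse to fine);
# four levels match the four-vector demons regularization defaults
PYRAMID_SCALES = (0.25, 0.5, 0.5, 1.0)
PYRAMID_CHANNELS = ("vessel", "vessel", "blend", "neuron")


@dataclass
class SessionSummary:
    vessel_proj: VesselImage
    neuron_proj: ProjectionImage
    noise_map: np.ndarray
    session_id: int = 0
    n_frames: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel_proj.values.shape


@dataclass
class BVScore:
    c_obs: float
    c_random: np.ndarray
    score: float


@dataclass
class AtlasSolution:
    pairwise_fields: dict[tuple[int, int], np.ndarray]
    weights: list[np.ndarray]
    to_atlas: list[np.ndarray]
    mode: str  # "bv+neuron" or "neuron-only"
    alerts: list[str] = dc_field(default_factory=list)


def _normalize01(img: np.ndarray) -> np.ndarray:
    span = np.ptp(img)
    if span == 0:
        return np.zeros_like(img)
    return (img - img.min()) / span


def build_session_summary(video: np.ndarray,
                          vessel_config: VesselFilterConfig | None = None,
                          fps: float = 10.0,
                          session_id: int = 0,
                          chunk_frames: int = 3000) -> SessionSummary:
    """Summarize a motion-corrected session for alignment.

    The vessel projection is the enhanced median frame (vessels live in the
    static baseline); the neuron projection is the elementwise product of
    the min-max-normalized correlation and PNR images of the detrended,
    noise-scaled video.
    """
    from .config import ExtractionConfig
    from .extract import seed_projections

    video = np.asarray(video, dtype=float)
    pre = detrend_and_scale(video, fps=fps, session_id=session_id)
    vessel = enhance_vessels(np.median(video, axis=0), vessel_config)
    # matched-filtered projections (same convention as seed finding), as
    # elementwise maxima over chunks: the plain max/sigma image is dominated
    # by the noise maximum statistic and carries little neuron contrast at
    # realistic peak-to-noise ratios
    corr = pnr = None
    for a in range(0, video.shape[0], chunk_frames):
        c_i, p_i, _ = seed_projections(pre.video[a:a + chunk_frames],
                                       ExtractionConfig())
        corr = c_i if corr is None else np.maximum(corr, c_i)
        pnr = p_i if pnr is None else np.maximum(pnr, p_i)
    neuron = _normalize01(corr) * _normalize01(pnr)
    return SessionSummary(
        vessel_proj=vessel,
        neuron_proj=ProjectionImage(values=neuron, kind="neuron"),
        noise_map=pre.noise_map,
        session_id=session_id,
        n_frames=video.shape[0],
    )


def bv_similarity_score(bv_a: np.ndarray, bv_b: np.ndarray,
                        n_surrogates: int = 100, seed: int = 0,
                        surrogate_sigma: float = 15.0,
                        surrogate_amplitude: float = 6.0) -> BVScore:
    """Z-score the observed vessel-map correlation against a null built by
    randomly misaligning one map (smooth fields, sigma 15, amplitude 6 px).

    A score above ~2.7 indicates vessel structure reliable enough to guide
    registration.
    """
    bv_a = np.asarray(bv_a, dtype=float)
    bv_b = np.asarray(bv_b, dtype=float)
    if bv_a.shape != bv_b.shape:
        raise ValueError("vessel maps must share shape")
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    if bv_a.std() == 0 or bv_b.std() == 0:
        raise ValueError("zero-variance vessel map")
    c_obs = float(np.corrcoef(bv_a.ravel(), bv_b.ravel())[0, 1])
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_surrogates)
    for i in range(n_surrogates):
        f = gradient_gaussian_field(bv_b.shape, surrogate_sigma,
                                    surrogate_amplitude, rng)
        warped = warp(bv_b, f)
        c_rand[i] = np.corrcoef(bv_a.ravel(), warped.ravel())[0, 1]
    sd = c_rand.std()
    score = (c_obs - c_rand.mean()) / sd if sd > 0 else np.inf
    return BVScore(c_obs=c_obs, c_random=c_rand, score=float(score))


def _channel(summary: SessionSummary, name: str) -> np.ndarray:
    if name == "vessel":
        return summary.vessel_proj.values
    if name == "neuron":
        return summary.neuron_proj.values
    if name == "blend":
        return 0.5 * (_normalize01(summary.vessel_proj.values)
                      + _normalize01(summary.neuron_proj.values))
    raise ValueError(f"unknown channel {name!r}")


def _resize_field(field: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Upsample/downsample a displacement field, rescaling magnitudes."""
    if field.shape[1:] == shape:
        return field
    fy = resize(field[0], shape, order=1, mode="edge", anti_aliasing=False)
    fx = resize(field[1], shape, order=1, mode="edge", anti_aliasing=False)
    fy *= shape[0] / field.shape[1]
    fx *= shape[1] / field.shape[2]
    return np.stack([fy, fx])


def multiscale_align_pair(summary_fixed: SessionSummary,
                          summary_moving: SessionSummary,
                          demons_config: DemonsConfig | None = None,
                          schedule: str = "bv+neuron") -> np.ndarray:
    """Coarse-to-fine registration of one session summary onto another.

    The returned field T satisfies warp(moving_proj, T) ~= fixed_proj at
    full resolution. ``schedule`` selects the per-level channel: the
    default starts on vessel projections and ends on neuron projections;
    ``"neuron-only"`` uses neuron projections at every level.
    """
    if demons_config is None:
        demons_config = DemonsConfig()
    if summary_fixed.shape != summary_moving.shape:
        raise ValueError("summaries must share shape")
    if schedule == "bv+neuron":
        channels = PYRAMID_CHANNELS
    elif schedule == "neuron-only":
        channels = ("neuron",) * len(PYRAMID_SCALES)
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    full = summary_fixed.shape
    field: np.ndarray | None = None
    for level, (scale, chan) in enumerate(zip(PYRAMID_SCALES, channels)):
        shape = (max(8, int(round(full[0] * scale))),
                 max(8, int(round(full[1] * scale))))
        F = resize(_channel(summary_fixed, chan), shape, mode="edge",
                   anti_aliasing=True)
        M = resize(_channel(summary_moving, chan), shape, mode="edge",
                   anti_aliasing=True)
        init = None if field is None else _resize_field(field, shape)
        try:
            field = log_demons_register(F, M, demons_config, level=level,
                                        init_field=init)
        except RegistrationDivergence:
            log.warning("level %d diverged; keeping previous level's field", level)
            field = init if init is not None else np.zeros((2,) + shape)
    assert field is not None
    return _resize_field(field, full)


def local_similarity_weights(aligned_vessel_projs: list[np.ndarray],
                             radius: int = 5) -> list[np.ndarray]:
    """Per-session, per-pixel weight maps from local structural similarity.

    Each session's map is the mean windowed SSIM against every other
    session, clipped to be nonnegative and normalized so the weights sum to
    N at every pixel (uniform weights equal 1).
    """
    n = len(aligned_vessel_projs)
    if n < 2:
        raise ValueError("need at least 2 sessions")
    win = 2 * radius + 1
    sims = []
    for s, proj_s in enumerate(aligned_vessel_projs):
        acc = np.zeros_like(np.asarray(proj_s, dtype=float))
        for i, proj_i in enumerate(aligned_vessel_projs):
            if i == s:
                continue
            both = np.stack([proj_s, proj_i])
            rng_ = np.ptp(both)
            _, ssim_map = structural_similarity(
                np.asarray(proj_s, float), np.asarray(proj_i, float),
                win_size=win, full=True, data_range=rng_ if rng_ > 0 else 1.0)
            acc += ssim_map
        sims.append(np.clip(acc / (n - 1), 1e-6, None))
    total = np.sum(sims, axis=0)
    weights = [n * s / total for s in sims]
    # smooth at the window scale: weight maps modulate displacement fields
    # pixelwise and sharp weight edges would destroy field smoothness
    weights = [ndimage.gaussian_filter(w, radius, mode="nearest") for w in weights]
    total = np.sum(weights, axis=0)
    return [n * w / total for w in weights]


def _pair_weight_map(bv_fixed: np.ndarray, bv_moving_aligned: np.ndarray,
                     radius: int = 5) -> np.ndarray:
    """Local post-alignment structural similarity of one session pair,
    clipped to be positive; low values mark regions (or whole pairs) whose
    transformation is unreliable."""
    both = np.stack([bv_fixed, bv_moving_aligned])
    rng_ = np.ptp(both)
    _, ssim_map = structural_similarity(
        np.asarray(bv_fixed, float), np.asarray(bv_moving_aligned, float),
        win_size=2 * radius + 1, full=True,
        data_range=rng_ if rng_ > 0 else 1.0)
    return ndimage.gaussian_filter(np.clip(ssim_map, 1e-3, None), radius,
                                   mode="nearest")


def groupwise_atlas(pairwise_fields: dict[tuple[int, int], np.ndarray],
                    vessel_projs: list[np.ndarray] | None = None,
                    weights: list[np.ndarray] | None = None,
                    n_sessions: int | None = None) -> AtlasSolution:
    """Map every session into a common atlas from the ordered pairwise fields.

    Each contribution T_(i->s) is weighted pixelwise by the post-alignment
    local vessel similarity of the pair (i, s), so an unreliable
    transformation between dissimilar sessions barely influences the atlas:

        T_(s->CA) = -((N-1)/N) * sum_i T_(i->s) w_is / sum_i w_is

    With uniform weights this reduces to the plain groupwise mean
    -(1/N) sum_i T_(i->s) (T_(s->s) = 0). When no vessel projections are
    supplied the supplied per-session weight maps (or uniform weights) are
    used for every contribution to session s.
    """
    if n_sessions is None:
        n_sessions = max(max(i, s) for i, s in pairwise_fields) + 1
    N = n_sessions
    shape = next(iter(pairwise_fields.values())).shape
    for s in range(N):
        for i in range(N):
            if i != s and (i, s) not in pairwise_fields:
                raise KeyError(f"missing pairwise field ({i}->{s})")

    pair_w: dict[tuple[int, int], np.ndarray] = {}
    for (i, s), T in pairwise_fields.items():
        if vessel_projs is not None:
            pair_w[(i, s)] = _pair_weight_map(vessel_projs[s],
                                              warp(vessel_projs[i], T))
        elif weights is not None:
            pair_w[(i, s)] = weights[s]
        else:
            pair_w[(i, s)] = np.ones(shape[1:])

    to_atlas = []
    for s in range(N):
        num = np.zeros(shape)
        den = np.zeros(shape[1:])
        for i in range(N):
            if i == s:
                continue
            w = pair_w[(i, s)]
            num += pairwise_fields[(i, s)] * w[None]
            den += w
        to_atlas.append(-(N - 1) / N * num / den[None])

    session_weights = weights
    if vessel_projs is not None:
        aligned = [warp(v, f) for v, f in zip(vessel_projs, to_atlas)]
        session_weights = local_similarity_weights(aligned)
    if session_weights is None:
        session_weights = [np.ones(shape[1:]) for _ in range(N)]

    for s in range(N):
        # a light diffusion pass guards against folding introduced by the
        # pixelwise weight modulation
        if not is_diffeomorphic(to_atlas[s]):
            to_atlas[s] = np.stack([
                ndimage.gaussian_filter(to_atlas[s][c], 2.0, mode="nearest")
                for c in range(2)])
        if not is_diffeomorphic(to_atlas[s]):
            raise RuntimeError(f"atlas field for session {s} folds")
    return AtlasSolution(pairwise_fields=pairwise_fields, weights=session_weights,
                         to_atlas=to_atlas, mode="bv+neuron")


def alignment_report(aligned_neuron_projs: list[np.ndarray]) -> dict:
    """Mean pairwise spatial correlation plus crispness of the mean projection."""
    n = len(aligned_neuron_projs)
    cors = []
    for i in range(n):
        for j in range(i + 1, n):
            a = aligned_neuron_projs[i].ravel()
            b = aligned_neuron_projs[j].ravel()
            if a.std() > 0 and b.std() > 0:
                cors.append(float(np.corrcoef(a, b)[0, 1]))
    return {
        "spatial_correlation": float(np.mean(cors)) if cors else 0.0,
        "crispness": crispness(np.mean(aligned_neuron_projs, axis=0)),
    }


def align_sessions(videos: list[np.ndarray],
                   vessel_config: VesselFilterConfig | None = None,
                   demons_config: DemonsConfig | None = None,
                   bv_threshold: float = BV_THRESHOLD_DEFAULT,
                   fps: float = 10.0,
                   seed: int = 0,
                   summaries: list[SessionSummary] | None = None,
                   n_refine_iters: int = 1,
                   ) -> tuple[list[np.ndarray], AtlasSolution, dict]:
    """Align >= 2 preprocessed sessions into a common atlas.

    Every ordered pair is registered with the vessel+neuron schedule; the
    vessel similarity score of the aligned pair decides whether that pair
    is re-registered neuron-only (score below ``bv_threshold``). If a
    session's mean pair score falls below the threshold the whole run
    switches to neuron-only and an alert is issued. The atlas fields are
    applied to every frame of every session.
    """
    if len(videos) < 2:
        raise ValueError("align_sessions needs at least 2 sessions")
    if summaries is None:
        summaries = [build_session_summary(v, vessel_config, fps=fps, session_id=i)
                     for i, v in enumerate(videos)]
    N = len(summaries)
    alerts: list[str] = []
    pair_fields: dict[tuple[int, int], np.ndarray] = {}
    pair_scores: dict[tuple[int, int], float] = {}
    pair_modes: dict[tuple[int, int], str] = {}

    for s in range(N):
        for i in range(N):
            if i == s:
                continue
            T = multiscale_align_pair(summaries[s], summaries[i], demons_config,
                                      schedule="bv+neuron")
            aligned_bv = warp(summaries[i].vessel_proj.values, T)
            score = bv_similarity_score(summaries[s].vessel_proj.values,
                                        aligned_bv, seed=seed + 7919 * i + s).score
            pair_scores[(i, s)] = score
            if score < bv_threshold:
                alerts.append(
                    f"pair ({i}->{s}) vessel score {score:.2f} < {bv_threshold}; "
                    f"using neuron-only registration for this pair")
                T = multiscale_align_pair(summaries[s], summaries[i], demons_config,
                                          schedule="neuron-only")
                pair_modes[(i, s)] = "neuron-only"
            else:
                pair_modes[(i, s)] = "bv+neuron"
            pair_fields[(i, s)] = T

    mode = "bv+neuron"
    mean_scores = []
    for s in range(N):
        vals = [v for (i, j), v in pair_scores.items() if j == s or i == s]
        mean_scores.append(float(np.mean(vals)))
    if any(m < bv_threshold for m in mean_scores):
        worst = int(np.argmin(mean_scores))
        mode = "neuron-only"
        alerts.append(
            f"session {worst} mean vessel score {mean_scores[worst]:.2f} < "
            f"{bv_threshold}; switching the whole run to neuron-only alignment")
        for key, m in pair_modes.items():
            if m != "neuron-only":
                pair_fields[key] = multiscale_align_pair(
                    summaries[key[1]], summaries[key[0]], demons_config,
                    schedule="neuron-only")
                pair_modes[key] = "neuron-only"

    vessel_projs = [s.vessel_proj.values for s in summaries]
    atlas = groupwise_atlas(pair_fields, vessel_projs=vessel_projs, n_sessions=N)
    atlas.mode = mode
    atlas.alerts = alerts

    # iterative refinement (only worthwhile beyond 2 sessions): once every
    # session has moved toward the common frame, session pairs that were too
    # far apart to register directly fall inside the registration basin, so
    # re-registering the atlas-aligned summaries and re-solving sharpens the
    # common frame
    for _ in range(n_refine_iters if N > 2 else 0):
        warped = []
        for s_i, summ in enumerate(summaries):
            f = atlas.to_atlas[s_i]
            warped.append(SessionSummary(
                vessel_proj=VesselImage(values=warp(summ.vessel_proj.values, f),
                                        scales_used=summ.vessel_proj.scales_used),
                neuron_proj=ProjectionImage(
                    values=warp(summ.neuron_proj.values, f), kind="neuron"),
                noise_map=summ.noise_map, session_id=summ.session_id,
                n_frames=summ.n_frames))
        refined: dict[tuple[int, int], np.ndarray] = {}
        for s in range(N):
            for i in range(N):
                if i != s:
                    refined[(i, s)] = multiscale_align_pair(
                        warped[s], warped[i], demons_config,
                        schedule="neuron-only" if mode == "neuron-only"
                        else pair_modes[(i, s)])
        atlas2 = groupwise_atlas(
            refined, vessel_projs=[w.vessel_proj.values for w in warped],
            n_sessions=N)
        atlas = AtlasSolution(
            pairwise_fields=pair_fields, weights=atlas2.weights,
            to_atlas=[compose_fields(f2, f1) for f1, f2
                      in zip(atlas.to_atlas, atlas2.to_atlas)],
            mode=mode, alerts=alerts)

    aligned_videos = [warp(v, f) for v, f in zip(videos, atlas.to_atlas)]
    neuron_pre = [s.neuron_proj.values for s in summaries]
    neuron_post = [warp(p, f) for p, f in zip(neuron_pre, atlas.to_atlas)]
    report = {
        "pair_scores": {f"{i}->{s}": v for (i, s), v in pair_scores.items()},
        "pair_modes": {f"{i}->{s}": v for (i, s), v in pair_modes.items()},
        "session_mean_scores": mean_scores,
        "mode": mode,
        "alerts": alerts,
        "pre_alignment": alignment_report(neuron_pre),
        "post_alignment": alignment_report(neuron_post),
    }
    return aligned_videos, atlas, report
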