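"""Seeded nonnegative factorization for concatenated multi-session stacks.

The model is Y(t) ~= C(t)^T A + B(t) with nonnegative footprints A, traces
C, and a background B = b0 + W . ring_mean(residual): diffuse out-of-focus
fluorescence at a pixel is predicted from the mean residual intensity on a
surrounding annulus, with a per-pixel gain W fitted by least squares.
Batches (default: one session) are factorized with shared footprints and
summarized into a single component set, so a neuron detected in any session
keeps one footprint row spanning the whole timeline.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, signal

from .config import ExtractionConfig
from .preprocess import estimate_noise
from .projections import correlation_image

__all__ = [
    "ComponentSet",
    "find_seed_pixels",
    "parallel_initialize",
    "cnmf_update",
    "extract_batchwise",
    "summarize_batches",
    "oasis_ar1",
]

log = logging.getLogger(__name__)


@dataclass
class ComponentSet:
    A: np.ndarray                 # K x P nonnegative footprints
    C: np.ndarray                 # K x T nonnegative denoised traces
    S: np.ndarray                 # K x T deconvolved event amplitudes
    W: np.ndarray                 # per-pixel ring-background gain map (H x W)
    B0: np.ndarray                # baseline image (H x W)
    fov_shape: tuple[int, int]
    per_batch_b0: list[np.ndarray] = dc_field(default_factory=list)
    objective_trace: list[float] = dc_field(default_factory=list)
    lineage: list[list[int]] | None = None  # output row -> input rows merged into it

    @property
    def n_components(self) -> int:
        return self.A.shape[0]

    def footprint_images(self) -> np.ndarray:
        return self.A.reshape((-1,) + tuple(self.fov_shape))

    def centroids(self) -> np.ndarray:
        imgs = self.footprint_images()
        h, w = self.fov_shape
        yy, xx = np.mgrid[0:h, 0:w]
        tot = imgs.sum(axis=(1, 2))
        tot[tot == 0] = 1.0
        cy = (imgs * yy).sum(axis=(1, 2)) / tot
        cx = (imgs * xx).sum(axis=(1, 2)) / tot
        return np.stack([cy, cx], axis=1)


# ---------------------------------------------------------------------------
# seeds

_SMOOTH_FRAMES = 5  # matched temporal filter width for seed projections
_MIN_INIT_SKEW = 0.5  # transient traces are right-skewed; noise fits are not


def spatial_bandpass(video: np.ndarray, gSig: float) -> np.ndarray:
    """Difference-of-Gaussians filter (center gSig, surround 2*gSig) per
    frame: suppresses both pixel noise and the smooth background so that
    neuron-sized structure dominates."""
    lo = ndimage.gaussian_filter(video, (0, gSig, gSig))
    hi = ndimage.gaussian_filter(video, (0, 2 * gSig, 2 * gSig))
    return lo - hi


def seed_projections(video: np.ndarray, config: ExtractionConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation and PNR images tuned for seed finding.

    Both are computed on the spatially band-passed, temporally
    matched-filtered (short boxcar) video. The PNR image divides the peak
    smoothed excursion by the *unsmoothed* spectral noise sigma, so that
    smoothing pulls the noise maxima well below the seed threshold while
    slow calcium transients keep most of their amplitude. Returns
    (corr, pnr, filtered video).
    """
    filt = spatial_bandpass(np.asarray(video, float), config.gSig)
    noise = np.maximum(estimate_noise(filt), 1e-9)
    sm = ndimage.uniform_filter1d(filt, _SMOOTH_FRAMES, axis=0)
    pnr = (sm - np.median(sm, axis=0)).max(axis=0) / noise
    corr = correlation_image(sm).values
    return corr, np.maximum(pnr, 0.0), filt


def find_seed_pixels(corr_img: np.ndarray, pnr_img: np.ndarray,
                     config: ExtractionConfig) -> np.ndarray:
    """Candidate neuron centers: local maxima of corr*pnr passing both
    thresholds, greedily thinned to a minimum spacing of gSig and ordered
    by descending PNR. Returns an (n, 2) array of (row, col)."""
    corr_img = np.asarray(corr_img, dtype=float)
    pnr_img = np.asarray(pnr_img, dtype=float)
    if corr_img.shape != pnr_img.shape:
        raise ValueError("correlation and PNR images must share shape")
    score = corr_img * pnr_img
    mask = (corr_img > config.min_corr) & (pnr_img > config.min_pnr)
    size = max(3, int(round(config.gSig)) | 1)
    is_max = score == ndimage.maximum_filter(score, size=size)
    cand = np.argwhere(mask & is_max & (score > 0))
    if cand.size == 0:
        return np.empty((0, 2), dtype=int)
    order = np.argsort(-pnr_img[cand[:, 0], cand[:, 1]], kind="stable")
    cand = cand[order]
    kept: list[np.ndarray] = []
    for c in cand:
        if all(np.hypot(*(c - k)) >= config.gSig for k in kept):
            kept.append(c)
    return np.array(kept, dtype=int)


# ---------------------------------------------------------------------------
# initialization


def _init_one_seed(resid: np.ndarray, seed_yx: tuple[int, int], radius: int
                   ) -> tuple[np.ndarray, np.ndarray, tuple[slice, slice]] | None:
    """Greedy rank-1 (a, c) from a seed's correlation neighborhood; returns
    footprint patch, trace and the patch slices, or None if degenerate."""
    T, h, w = resid.shape
    y, x = seed_yx
    ys = slice(max(0, y - radius), min(h, y + radius + 1))
    xs = slice(max(0, x - radius), min(w, x + radius + 1))
    patch = resid[:, ys, xs]
    y_seed = resid[:, max(0, y - 1):y + 2, max(0, x - 1):x + 2].mean(axis=(1, 2))
    var = y_seed.var()
    if var <= 0:
        return None
    yc = y_seed - y_seed.mean()
    a = np.tensordot(patch - patch.mean(axis=0), yc, axes=(0, 0)) / (var * T)
    a = np.clip(a, 0.0, None)
    if a.max() <= 0:
        return None
    for _ in range(2):
        c = np.tensordot(patch, a, axes=([1, 2], [0, 1])) / (a * a).sum()
        c = np.clip(c, 0.0, None)
        cc = (c * c).sum()
        if cc == 0:
            return None
        a = np.clip(np.tensordot(patch, c, axes=(0, 0)) / cc, 0.0, None)
        if a.max() <= 0:
            return None
    peak = a.max()
    a = a / peak
    c = c * peak
    return a, c, (ys, xs)


def _patch_grid(shape: tuple[int, int], n_patches: int) -> list[tuple[slice, slice]]:
    h, w = shape
    rows = max(1, int(round(np.sqrt(n_patches * h / w))))
    cols = max(1, int(np.ceil(n_patches / rows)))
    ys = np.linspace(0, h, rows + 1).astype(int)
    xs = np.linspace(0, w, cols + 1).astype(int)
    return [(slice(ys[r], ys[r + 1]), slice(xs[c], xs[c + 1]))
            for r in range(rows) for c in range(cols)]


def _skewness(x: np.ndarray) -> float:
    sd = x.std()
    if sd == 0:
        return 0.0
    return float(((x - x.mean()) ** 3).mean() / sd ** 3)


def parallel_initialize(video: np.ndarray, seeds: np.ndarray,
                        config: ExtractionConfig,
                        filtered: np.ndarray | None = None,
                        min_skew: float = _MIN_INIT_SKEW) -> ComponentSet:
    """Initialize components from seeds, processing distant FOV patches
    concurrently.

    The rank-1 fits run on the band-passed video (``filtered``; computed
    here when not supplied) so the shared background cannot leak into
    footprints. Candidates whose trace skewness falls below ``min_skew``
    are rejected: genuine transients are right-skewed, noise fits are not.

    The FOV is tiled (targeting ``config.n_patches`` patches) with a margin
    of 2*gSiz; within a patch seeds are initialized sequentially from high
    to low PNR, each subtracted from the patch residual before the next.
    Patches share no state, so the result does not depend on processing
    order and matches fully sequential initialization for seeds farther
    apart than the margin.
    """
    video = np.asarray(video, dtype=float)
    if filtered is None:
        filtered = spatial_bandpass(video, config.gSig)
    T, h, w = video.shape
    noise_filt = np.maximum(estimate_noise(filtered), 1e-9)
    gsiz = config.resolved_gsiz()
    margin = int(np.ceil(2 * gsiz))
    radius = int(np.ceil(gsiz))
    patches = _patch_grid((h, w), config.n_patches)

    def run_patch(core: tuple[slice, slice]):
        ys, xs = core
        py0, py1 = max(0, ys.start - margin), min(h, ys.stop + margin)
        px0, px1 = max(0, xs.start - margin), min(w, xs.stop + margin)
        local_seeds = [s for s in seeds
                       if ys.start <= s[0] < ys.stop and xs.start <= s[1] < xs.stop]
        if not local_seeds:
            return []
        resid = filtered[:, py0:py1, px0:px1].copy()
        found = []
        for s in local_seeds:  # already ordered high-to-low PNR globally
            sy0, sx0 = s[0] - py0, s[1] - px0
            # re-validate the seed on the current residual: earlier
            # initializations may have already explained its signal
            tr = ndimage.uniform_filter1d(resid[:, sy0, sx0], _SMOOTH_FRAMES)
            rpnr = (tr.max() - np.median(tr)) / noise_filt[s[0], s[1]]
            if rpnr < config.min_pnr:
                continue
            out = _init_one_seed(resid, (sy0, sx0), radius)
            if out is None:
                log.info("seed at %s skipped: degenerate neighborhood", tuple(s))
                continue
            a, c, (sy, sx) = out
            if _skewness(c) < min_skew:
                continue
            resid[:, sy, sx] -= c[:, None, None] * a[None]
            full = np.zeros((h, w))
            full[py0 + sy.start:py0 + sy.stop, px0 + sx.start:px0 + sx.stop] = a
            found.append((full.ravel(), c))
        return found

    with ThreadPoolExecutor(max_workers=min(4, len(patches))) as ex:
        results = list(ex.map(run_patch, patches))
    comps = [item for patch_items in results for item in patch_items]
    comps = comps[: config.max_components]
    if comps:
        A = np.array([a for a, _ in comps])
        C = np.array([c for _, c in comps])
    else:
        A = np.empty((0, h * w))
        C = np.empty((0, T))
    return ComponentSet(A=A, C=C, S=np.zeros_like(C), W=np.zeros((h, w)),
                        B0=np.zeros((h, w)), fov_shape=(h, w))


# ---------------------------------------------------------------------------
# deconvolution


def estimate_ar1_coeff(y: np.ndarray) -> float:
    """AR(1) coefficient from the trace autocovariance ratio
    gamma = acov(2) / acov(1); clipped to a stable range."""
    yc = y - y.mean()
    T = len(yc)
    if T < 5:
        return 0.9
    a1 = (yc[:-1] * yc[1:]).sum() / T
    a2 = (yc[:-2] * yc[2:]).sum() / T
    if a1 <= 0:
        return 0.9
    return float(np.clip(a2 / a1, 0.3, 0.99))


def oasis_ar1(y: np.ndarray, g: float) -> tuple[np.ndarray, np.ndarray]:
    """Online active-set AR(1) deconvolution (pool adjacent violators).

    Solves min ||c - y||^2 s.t. s_t = c_t - g c_{t-1} >= 0, c >= 0.
    Returns (denoised c, deconvolved s).
    """
    y = np.asarray(y, dtype=float)
    # pools: [value, weight, start, length]
    pools: list[list[float]] = []
    for t, yt in enumerate(y):
        pools.append([yt, 1.0, t, 1])
        while len(pools) > 1:
            v1, w1, t1, l1 = pools[-2]
            v2, w2, t2, l2 = pools[-1]
            if v2 >= g ** l1 * v1:
                break
            gl = g ** l1
            w_new = w1 + gl * gl * w2
            v_new = (w1 * v1 + gl * w2 * v2) / w_new
            pools[-2] = [v_new, w_new, t1, l1 + l2]
            pools.pop()
    c = np.zeros_like(y)
    for v, _, t0, l in pools:
        v = max(v, 0.0)
        c[int(t0):int(t0) + int(l)] = v * g ** np.arange(int(l))
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - g * c[:-1]
    return c, np.clip(s, 0.0, None)


_SPIKE_THRESHOLD_SIGMA = 1.5   # noise-referenced event floor
_SPIKE_THRESHOLD_FRAC = 0.25   # cap relative to the trace's largest event


def deconvolve_traces(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deconvolve each trace with its own AR(1) coefficient.

    Sub-threshold events are zeroed and the denoised trace rebuilt from the
    surviving events, which removes most noise bumps that the plain
    isotonic solution keeps. The threshold is 1.5 trace-noise sigma, capped
    at a quarter of the trace's largest event: traces with many overlapping
    transients peak-normalize to small individual events, and a purely
    noise-referenced floor would discard genuine activity there. Traces
    that fail keep their raw values with S = 0.
    """
    C_out = np.empty_like(C)
    S_out = np.zeros_like(C)
    for k in range(C.shape[0]):
        try:
            y = C[k]
            g = estimate_ar1_coeff(y)
            _, s = oasis_ar1(y, g)
            sigma = estimate_noise(y[:, None, None]).item()
            thr = _SPIKE_THRESHOLD_SIGMA * sigma
            if s.max() > 0:
                thr = min(thr, _SPIKE_THRESHOLD_FRAC * s.max())
            s[s < thr] = 0.0
            C_out[k] = signal.lfilter([1.0], [1.0, -g], s)
            S_out[k] = s
        except Exception:  # pragma: no cover - defensive
            warnings.warn(f"deconvolution failed for component {k}; keeping raw trace")
            C_out[k] = C[k]
    return C_out, S_out


# ---------------------------------------------------------------------------
# factorization


def _ring_kernel(radius: float, width: float = 2.0) -> np.ndarray:
    r_out = radius + width / 2.0
    r_in = max(0.5, radius - width / 2.0)
    n = int(np.ceil(r_out))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    rr = np.hypot(yy, xx)
    ker = ((rr <= r_out) & (rr >= r_in)).astype(float)
    return ker / ker.sum()


def _ring_background(resid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Annulus-mean of the residual around every pixel, per frame (FFT)."""
    return signal.fftconvolve(resid, kernel[None], mode="same", axes=(1, 2))


def _update_background(Y: np.ndarray, A: np.ndarray, C: np.ndarray,
                       kernel: np.ndarray, shape: tuple[int, int]
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit b0 + W . ring_mean(residual) by per-pixel least squares on the
    neuron-subtracted residual. Returns (B (T,P), W map, b0 map)."""
    T = Y.shape[0]
    resid = Y - C.T @ A if A.size else Y.copy()
    b0 = np.median(resid, axis=0)
    resid0 = (resid - b0[None]).reshape((T,) + shape)
    X = _ring_background(resid0, kernel).reshape(T, -1)
    R = resid - b0[None]
    denom = (X * X).sum(axis=0)
    wmap = np.where(denom > 0, (R * X).sum(axis=0) / np.maximum(denom, 1e-12), 0.0)
    wmap = np.clip(wmap, 0.0, 2.0)
    B = b0[None] + wmap[None] * X
    return B, wmap.reshape(shape), b0.reshape(shape)


def _hals_temporal(Y: np.ndarray, A: np.ndarray, C: np.ndarray,
                   B: np.ndarray, n_passes: int = 2) -> np.ndarray:
    """Trace-only HALS refinement with footprints held fixed."""
    R = Y - C.T @ A - B
    for _ in range(n_passes):
        for k in range(A.shape[0]):
            na = (A[k] * A[k]).sum()
            if na > 0:
                c_new = np.clip(C[k] + R @ A[k] / na, 0.0, None)
                R -= np.outer(c_new - C[k], A[k])
                C[k] = c_new
    return C


def _hals(Y: np.ndarray, A: np.ndarray, C: np.ndarray, B: np.ndarray,
          supports: np.ndarray, n_passes: int = 1) -> tuple[np.ndarray, np.ndarray, float]:
    """Hierarchical alternating least squares on C then A (support-restricted),
    keeping both nonnegative. Returns updated (A, C, ||R||^2)."""
    R = Y - C.T @ A - B
    for _ in range(n_passes):
        for k in range(A.shape[0]):
            na = (A[k] * A[k]).sum()
            if na > 0:
                c_new = np.clip(C[k] + R @ A[k] / na, 0.0, None)
                R -= np.outer(c_new - C[k], A[k])
                C[k] = c_new
        for k in range(A.shape[0]):
            nc = (C[k] * C[k]).sum()
            if nc > 0:
                a_new = np.clip(A[k] + C[k] @ R / nc, 0.0, None) * supports[k]
                R -= np.outer(C[k], a_new - A[k])
                A[k] = a_new
    return A, C, float((R * R).sum())


def _dilated_supports(A: np.ndarray, shape: tuple[int, int], dil: int) -> np.ndarray:
    if not A.size:
        return np.empty((0, shape[0] * shape[1]), dtype=bool)
    struct = ndimage.generate_binary_structure(2, 1)
    return np.array([
        ndimage.binary_dilation(a.reshape(shape) > 0, struct, iterations=dil).ravel()
        for a in A
    ])


def _merge_components(A: np.ndarray, C: np.ndarray, threshold: float
                      ) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Union-find merge of spatially overlapping components whose traces
    correlate above ``threshold``. Returns (A, C, groups) where groups
    lists the input rows fused into each output row."""
    K = A.shape[0]
    parent = list(range(K))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(K):
        for j in range(i + 1, K):
            if (A[i] * A[j]).sum() <= 0:
                continue
            ci, cj = C[i], C[j]
            if ci.std() == 0 or cj.std() == 0:
                continue
            if np.corrcoef(ci, cj)[0, 1] > threshold:
                parent[find(j)] = find(i)
    groups_map: dict[int, list[int]] = {}
    for i in range(K):
        groups_map.setdefault(find(i), []).append(i)
    groups = list(groups_map.values())
    if len(groups) == K:
        return A, C, groups
    A_new, C_new = [], []
    for members in groups:
        if len(members) == 1:
            A_new.append(A[members[0]])
            C_new.append(C[members[0]])
        else:
            amps = np.array([C[m].max() for m in members])
            amps = amps / max(amps.sum(), 1e-12)
            a = sum(A[m] for m in members)
            c = sum(wgt * C[m] for wgt, m in zip(amps, members))
            peak = a.max()
            if peak > 0:
                a, c = a / peak, c * peak
            A_new.append(a)
            C_new.append(c)
    return np.array(A_new), np.array(C_new), groups


def cnmf_update(video: np.ndarray, components: ComponentSet,
                config: ExtractionConfig, n_iters: int | None = None,
                deconvolve: bool = True) -> ComponentSet:
    """Iterate background, temporal, and spatial updates on an initialized
    component set; merge correlated overlapping components; drop empties;
    finish with AR(1) deconvolution.

    The quadratic objective after each iteration's HALS pass is logged in
    ``objective_trace`` (non-increasing by construction of HALS).
    """
    config.validate()
    if n_iters is None:
        n_iters = config.n_iters
    video = np.asarray(video, dtype=float)
    T, h, w = video.shape
    Y = video.reshape(T, -1)
    A = components.A.copy()
    C = components.C.copy()
    gsiz = config.resolved_gsiz()
    kernel = _ring_kernel(config.resolved_ring_radius())
    dil = max(1, int(round(config.gSig)))
    supports = _dilated_supports(A, (h, w), dil)

    # merge duplicates before demixing: initial traces of components seeded
    # on one neuron still share that neuron's transients, so the trace
    # correlation identifies them; after HALS they would partition the
    # signal and become hard to recognize as duplicates
    lineage: list[list[int]] = [[k] for k in range(A.shape[0])]
    if A.shape[0] and C.any():
        A, C, lineage = _merge_components(A, C, config.merge_corr_threshold)
        supports = _dilated_supports(A, (h, w), dil)

    objective: list[float] = []
    B = np.zeros_like(Y)
    Wmap = np.zeros((h, w))
    b0 = np.zeros((h, w))
    for _ in range(n_iters):
        B, Wmap, b0 = _update_background(Y, A, C, kernel, (h, w))
        A, C, obj = _hals(Y, A, C, B, supports, n_passes=1)
        objective.append(obj)
    if A.size:
        A, C, groups = _merge_components(A, C, config.merge_corr_threshold)
        lineage = [sorted(set(m for g in grp for m in lineage[g])) for grp in groups]
        keep = (A.sum(axis=1) > 0) & (C.sum(axis=1) > 0)
        A, C = A[keep], C[keep]
        lineage = [g for g, kp in zip(lineage, keep) if kp]
        # support bound: clip footprints to a (3*gSiz)^2 box around the peak
        half = int(np.ceil(1.5 * gsiz))
        for k in range(A.shape[0]):
            img = A[k].reshape(h, w)
            py, px = np.unravel_index(np.argmax(img), (h, w))
            box = np.zeros((h, w), dtype=bool)
            box[max(0, py - half):py + half + 1, max(0, px - half):px + half + 1] = True
            A[k] = (img * box).ravel()
    if deconvolve and A.size:
        C, S = deconvolve_traces(C)
    else:
        S = np.zeros_like(C)
    out = ComponentSet(A=A, C=C, S=S, W=Wmap, B0=b0, fov_shape=(h, w),
                       objective_trace=objective, lineage=lineage)
    return out


# ---------------------------------------------------------------------------
# batchwise processing


def _batch_bounds(session_bounds: list[tuple[int, int]], batch_frames: int
                  ) -> list[tuple[int, int]]:
    out = []
    for a, b in session_bounds:
        if b - a <= batch_frames:
            out.append((a, b))
        else:
            t = a
            while t < b:
                out.append((t, min(t + batch_frames, b)))
                t += batch_frames
    return out


def summarize_batches(batch_results: list[dict], T_total: int,
                      n_components: int) -> ComponentSet:
    """Fuse per-batch factorizations into one component set.

    Ring gains W are averaged, the baseline B0 is the elementwise minimum
    across batches, footprints are averaged weighted by the squared mean
    temporal activity of each batch, and traces/events are concatenated in
    batch order (zeros where a component did not yet exist).
    """
    if not batch_results:
        raise ValueError("no batches to summarize")
    shape = batch_results[0]["shape"]
    P = shape[0] * shape[1]
    num = np.zeros((n_components, P))
    den = np.zeros(n_components)
    C = np.zeros((n_components, T_total))
    S = np.zeros((n_components, T_total))
    Wmaps, b0s = [], []
    for res in batch_results:
        if res["A"].shape[0] != len(res["ids"]):
            raise ValueError("component count mismatch within a batch result")
        a, b = res["bounds"]
        for row, k in enumerate(res["ids"]):
            wgt = float(res["C"][row].mean()) ** 2
            num[k] += wgt * res["A"][row]
            den[k] += wgt
            C[k, a:b] = res["C"][row]
            S[k, a:b] = res["S"][row]
        Wmaps.append(res["W"])
        b0s.append(res["B0"])
    A = np.zeros((n_components, P))
    zero_wgt = den == 0
    if zero_wgt.any():
        warnings.warn("components with all-zero batch activity: using unweighted mean")
    for k in range(n_components):
        rows = [res["A"][list(res["ids"]).index(k)]
                for res in batch_results if k in res["ids"]]
        if den[k] > 0:
            A[k] = num[k] / den[k]
        elif rows:
            A[k] = np.mean(rows, axis=0)
    return ComponentSet(A=A, C=C, S=S, W=np.mean(Wmaps, axis=0),
                        B0=np.min(b0s, axis=0), fov_shape=shape,
                        per_batch_b0=b0s)


def extract_batchwise(stack, session_bounds: list[tuple[int, int]] | None,
                      config: ExtractionConfig,
                      ) -> tuple[ComponentSet, dict]:
    """Memory-bounded extraction from a concatenated stack.

    Seeds come from the chunked-max correlation image over the whole stack;
    each batch (one session, or ``batch_frames`` within long sessions)
    augments the component set from its residual and refines all components
    by factorization; results are fused by :func:`summarize_batches`. At
    most one batch of frames is resident at a time; the peak count is
    reported in the info dict.
    """
    config.validate()
    T = stack.shape[0]
    h, w = stack.shape[1:]
    if session_bounds is None:
        session_bounds = [(0, T)]
    bounds = _batch_bounds(session_bounds, config.batch_frames)
    max_resident = 0

    def _centroids_of(A_mat: np.ndarray) -> list[np.ndarray]:
        yy, xx = np.mgrid[0:h, 0:w]
        cents = []
        for arow in A_mat:
            img = arow.reshape(h, w)
            tot = max(img.sum(), 1e-12)
            cents.append(np.array([(img * yy).sum() / tot, (img * xx).sum() / tot]))
        return cents

    batch_results: list[dict] = []
    A = np.empty((0, h * w))
    next_id = 0
    ids: list[int] = []
    for a, b in bounds:
        Yb = np.asarray(stack[a:b], dtype=float)
        max_resident = max(max_resident, Yb.shape[0])
        # fit existing components to this batch, then seed from the residual
        if A.shape[0]:
            pre = ComponentSet(A=A, C=np.zeros((A.shape[0], b - a)),
                               S=np.zeros((A.shape[0], b - a)), W=np.zeros((h, w)),
                               B0=np.zeros((h, w)), fov_shape=(h, w))
            fitted = cnmf_update(Yb, pre, config, n_iters=1, deconvolve=False)
            resid = Yb - (fitted.C.T @ fitted.A).reshape(Yb.shape)
        else:
            resid = Yb
        ci, pnr, filt = seed_projections(resid, config)
        seeds = find_seed_pixels(ci, pnr, config)
        # residual seeds hugging an existing component are alignment/fit
        # leftovers, not new neurons; veto within half a neuron diameter
        veto = max(config.gSig, config.resolved_gsiz() / 2.0)
        cents = _centroids_of(A)
        seeds = np.array([s for s in seeds
                          if all(np.hypot(*(s - c)) >= veto for c in cents)],
                         dtype=int).reshape(-1, 2)
        init = parallel_initialize(resid, seeds, config, filtered=filt)
        if init.n_components:
            ids = ids + list(range(next_id, next_id + init.n_components))
            next_id += init.n_components
            A = np.vstack([A, init.A]) if A.size else init.A
        if not A.shape[0]:
            batch_results.append(dict(A=np.empty((0, h * w)), C=np.empty((0, b - a)),
                                      S=np.empty((0, b - a)), W=np.zeros((h, w)),
                                      B0=np.zeros((h, w)), ids=[], bounds=(a, b),
                                      shape=(h, w)))
            continue
        pre = ComponentSet(A=A.copy(), C=np.zeros((A.shape[0], b - a)),
                           S=np.zeros((A.shape[0], b - a)), W=np.zeros((h, w)),
                           B0=np.zeros((h, w)), fov_shape=(h, w))
        # raw traces here; the unified sweep below deconvolves once, full-length
        res = cnmf_update(Yb, pre, config, deconvolve=False)
        # merging/dropping within the batch is tracked through the lineage;
        # a fused component keeps the id of its first (strongest) member
        kept_ids = [ids[group[0]] for group in (res.lineage or [])]
        batch_results.append(dict(A=res.A, C=res.C, S=res.S, W=res.W, B0=res.B0,
                                  ids=kept_ids, bounds=(a, b), shape=(h, w)))
        A = res.A
        ids = kept_ids

    # compact ids to a dense range
    unique = sorted(set(i for res in batch_results for i in res["ids"]))
    remap = {old: new for new, old in enumerate(unique)}
    for res in batch_results:
        res["ids"] = [remap[i] for i in res["ids"]]
    comps = summarize_batches(batch_results, T, len(unique))

    # unified temporal sweep: refit every trace against the fused footprints
    # batch by batch, then deconvolve the full-length traces once, so a
    # neuron barely active in one session still benefits from the footprint
    # estimated where it was strong
    if comps.n_components:
        kernel = _ring_kernel(config.resolved_ring_radius())
        C_raw = np.zeros_like(comps.C)
        for a, b in bounds:
            Yb = np.asarray(stack[a:b], dtype=float).reshape(b - a, -1)
            max_resident = max(max_resident, b - a)
            Cb = comps.C[:, a:b].copy()
            B, _, _ = _update_background(Yb, comps.A, Cb, kernel, (h, w))
            C_raw[:, a:b] = _hals_temporal(Yb, comps.A, Cb, B)
        comps.C, comps.S = deconvolve_traces(C_raw)
        # component-level quality gate, same convention as seed finding:
        # the matched-filtered raw trace must clear min_pnr in its own
        # noise units, and at least one deconvolved event must survive
        keep = np.ones(comps.n_components, dtype=bool)
        for k in range(comps.n_components):
            tr = ndimage.uniform_filter1d(C_raw[k], _SMOOTH_FRAMES)
            sig = estimate_noise(C_raw[k][:, None, None]).item()
            q = (tr.max() - np.median(tr)) / max(sig, 1e-12)
            keep[k] = (q >= config.min_pnr) and comps.S[k].max() > 0
        if not keep.all():
            comps = ComponentSet(A=comps.A[keep], C=comps.C[keep], S=comps.S[keep],
                                 W=comps.W, B0=comps.B0, fov_shape=comps.fov_shape,
                                 per_batch_b0=comps.per_batch_b0)

    info = {"max_resident_frames": max_resident, "batch_bounds": bounds,
            "n_batches": len(bounds)}
    return comps, info
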