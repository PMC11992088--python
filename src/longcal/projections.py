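"""Session projections: correlation image, PNR image, chunked-max
correlation, and the crispness sharpness metric.

The correlation image highlights active neurons because pixels inside one
cell share a time course; the PNR image highlights pixels whose peak
excursion is large relative to their noise floor. Both are the substrate
for seed finding and for the neuron channel used in alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProjectionImage",
    "correlation_image",
    "pnr_image",
    "chunked_max_correlation",
    "crispness",
]

_MIN_TAIL_CHUNK = 100


@dataclass
class ProjectionImage:
    values: np.ndarray
    kind: str  # correlation | pnr | neuron | vessel
    chunk_size: int | None = None


def correlation_image(video: np.ndarray, neighborhood: int = 8) -> ProjectionImage:
    """Mean Pearson correlation of each pixel's time series with its
    adjacent neighbors (8-connected by default, 4-connected on request).
    Zero-variance pixels contribute 0.
    """
    video = np.asarray(video, dtype=float)
    if video.ndim != 3 or video.shape[0] < 2:
        raise ValueError("correlation_image expects a (T, H, W) video with T >= 2")
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    T, h, w = video.shape
    mu = video.mean(axis=0)
    sd = video.std(axis=0)
    z = np.zeros_like(video)
    good = sd > 0
    z[:, good] = (video[:, good] - mu[good]) / sd[good]
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dy, dx) != (0, 0)
               and (neighborhood == 8 or abs(dy) + abs(dx) == 1)]
    for dy, dx in offsets:
        ys = slice(max(0, dy), h + min(0, dy))
        xs = slice(max(0, dx), w + min(0, dx))
        yn = slice(max(0, -dy), h + min(0, -dy))
        xn = slice(max(0, -dx), w + min(0, -dx))
        acc[ys, xs] += (z[:, ys, xs] * z[:, yn, xn]).mean(axis=0)
        cnt[ys, xs] += 1
    values = acc / cnt
    values[~good] = 0.0
    return ProjectionImage(values=np.clip(values, -1.0, 1.0), kind="correlation")


def pnr_image(video: np.ndarray, noise_map: np.ndarray) -> ProjectionImage:
    """Peak-to-noise ratio: per pixel, max over time of the median-centered
    series divided by its noise sigma."""
    video = np.asarray(video, dtype=float)
    noise_map = np.asarray(noise_map, dtype=float)
    if np.any(noise_map <= 0):
        raise ValueError("noise_map must be positive everywhere")
    med = np.median(video, axis=0)
    values = ((video - med[None]) / noise_map[None]).max(axis=0)
    return ProjectionImage(values=np.maximum(values, 0.0), kind="pnr")


def _chunk_bounds(T: int, chunk_frames: int) -> list[tuple[int, int]]:
    bounds = []
    t = 0
    while t < T:
        bounds.append((t, min(t + chunk_frames, T)))
        t += chunk_frames
    # fold a short tail into the previous chunk
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < _MIN_TAIL_CHUNK:
        a, _ = bounds.pop()
        prev_a, _ = bounds.pop()
        bounds.append((prev_a, T))
    return bounds


def chunked_max_correlation(video, chunk_frames: int = 3000) -> ProjectionImage:
    """Elementwise maximum of per-chunk correlation images.

    A neuron active only within one chunk keeps its full local correlation
    there, whereas the whole-video correlation dilutes it; peak memory is
    bounded by one chunk. ``video`` may be any sliceable (T, H, W) array
    (e.g. an HDF5 dataset).
    """
    if chunk_frames < 2:
        raise ValueError("chunk_frames must be >= 2")
    T = video.shape[0]
    out: np.ndarray | None = None
    for a, b in _chunk_bounds(T, chunk_frames):
        ci = correlation_image(np.asarray(video[a:b], dtype=float)).values
        out = ci if out is None else np.maximum(out, ci)
    assert out is not None
    return ProjectionImage(values=out, kind="correlation", chunk_size=chunk_frames)


def crispness(mean_projection: np.ndarray) -> float:
    """Mean gradient magnitude of the min-max-normalized projection; an
    alignment-quality score (blur from residual misalignment lowers it)."""
    img = np.asarray(mean_projection, dtype=float)
    span = np.ptp(img)
    if span == 0:
        return 0.0
    img = (img - img.min()) / span
    gy, gx = np.gradient(img)
    return float(np.hypot(gy, gx).mean())
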