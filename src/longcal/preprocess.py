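"""Per-session detrending, per-pixel noise scaling, downsampling, and
artifact-free concatenation.

Sessions recorded on different days differ in baseline fluorescence; naive
concatenation leaves intensity steps at session junctions that bleed into
the factorization. Removing each pixel's slow trend and dividing by its
noise sigma puts all sessions in common noise-scaled units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PreprocessedSession",
    "spatial_downsample",
    "estimate_noise",
    "detrend_and_scale",
    "concatenate_sessions",
]


@dataclass
class PreprocessedSession:
    video: np.ndarray          # (T, H, W) noise-scaled units
    noise_map: np.ndarray      # per-pixel sigma in original units
    baseline_removed: np.ndarray  # per-pixel mean of the removed trend
    session_id: int = 0


def spatial_downsample(video: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample each frame by an integer factor; trailing rows
    or columns that do not fill a block are cropped with a warning."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    video = np.asarray(video, dtype=float)
    if factor == 1:
        return video
    T, h, w = video.shape
    hc, wc = (h // factor) * factor, (w // factor) * factor
    if (hc, wc) != (h, w):
        warnings.warn(f"cropping frame from {h}x{w} to {hc}x{wc} for downsampling")
        video = video[:, :hc, :wc]
    return video.reshape(T, hc // factor, factor, wc // factor, factor).mean(axis=(2, 4))


def estimate_noise(video: np.ndarray, freq_range: tuple[float, float] = (0.25, 0.5)
                   ) -> np.ndarray:
    """Per-pixel noise sigma from the high-frequency half of the power
    spectrum (CNMF convention): for white noise E|X_k|^2 = T sigma^2 for
    every non-DC bin, so sigma = sqrt(mean_k |X_k|^2 / T) over bins with
    normalized frequency in ``freq_range``."""
    video = np.asarray(video, dtype=float)
    T = video.shape[0]
    freqs = np.fft.rfftfreq(T)
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    if not sel.any():
        raise ValueError("video too short for spectral noise estimation")
    spec = np.abs(np.fft.rfft(video - video.mean(axis=0), axis=0)[sel]) ** 2
    return np.sqrt(spec.mean(axis=0) / T)


def _running_percentile_baseline(video: np.ndarray, window: int, q: float = 20.0
                                 ) -> np.ndarray:
    """Piecewise running percentile: per-block percentiles linearly
    interpolated across time (O(T) instead of a sliding filter)."""
    T = video.shape[0]
    half = max(2, window // 2)
    starts = np.arange(0, T, half)
    centers = np.minimum(starts + half // 2, T - 1).astype(float)
    percs = np.stack([
        np.percentile(video[a : min(a + window, T)], q, axis=0) for a in starts
    ])
    out = np.empty_like(video)
    t = np.arange(T, dtype=float)
    # vectorized linear interpolation over block centers per pixel
    idx = np.clip(np.searchsorted(centers, t) - 1, 0, len(centers) - 2)
    c0, c1 = centers[idx], centers[idx + 1]
    w1 = np.clip((t - c0) / np.maximum(c1 - c0, 1e-12), 0.0, 1.0)
    out = percs[idx] * (1.0 - w1)[:, None, None] + percs[idx + 1] * w1[:, None, None]
    return out


def detrend_and_scale(video: np.ndarray, fps: float = 10.0,
                      window_s: float = 30.0, session_id: int = 0
                      ) -> PreprocessedSession:
    """Subtract a running 20th-percentile baseline (30 s window) per pixel
    and divide by the spectral noise sigma; zero-noise pixels are floored
    at a machine-scaled epsilon with a warning."""
    video = np.asarray(video, dtype=float)
    T = video.shape[0]
    window = max(4, int(round(window_s * fps)))
    if T <= 4:
        baseline = np.broadcast_to(np.percentile(video, 20.0, axis=0), video.shape)
    else:
        baseline = _running_percentile_baseline(video, min(window, T))
    detrended = video - baseline
    sigma = estimate_noise(detrended)
    floor = 1e3 * np.finfo(float).eps * max(1.0, float(np.abs(video).max()))
    dead = sigma <= floor
    if dead.any():
        warnings.warn("zero-noise pixels floored during noise scaling")
        sigma = np.maximum(sigma, floor)
        # such pixels carry no signal beyond float rounding; report them as 0
        detrended[:, dead] = 0.0
    return PreprocessedSession(
        video=detrended / sigma,
        noise_map=sigma,
        baseline_removed=baseline.mean(axis=0),
        session_id=session_id,
    )


@dataclass
class SessionIndex:
    """Frame bookkeeping for a concatenated stack."""

    session_ids: list[int]
    bounds: list[tuple[int, int]]
    junction_gaps: list[float] = field(default_factory=list)
    junction_threshold: float | None = None

    @property
    def n_frames(self) -> int:
        return self.bounds[-1][1] if self.bounds else 0

    def split(self, stack: np.ndarray) -> list[np.ndarray]:
        return [stack[a:b] for a, b in self.bounds]


def concatenate_sessions(sessions: list[PreprocessedSession | np.ndarray]
                         ) -> tuple[np.ndarray, SessionIndex]:
    """Temporally concatenate aligned, detrended sessions.

    Also reports the junction-artifact metric: mean |first frame of next -
    last frame of previous| at each boundary, compared against the 99th
    percentile of within-session adjacent-frame differences. The check is
    reported, not enforced.
    """
    arrays = [s.video if isinstance(s, PreprocessedSession) else np.asarray(s, float)
              for s in sessions]
    ids = [s.session_id if isinstance(s, PreprocessedSession) else i
           for i, s in enumerate(sessions)]
    shape = arrays[0].shape[1:]
    for a in arrays:
        if a.shape[1:] != shape:
            raise ValueError("all sessions must share spatial shape")
    bounds = []
    t = 0
    for a in arrays:
        bounds.append((t, t + a.shape[0]))
        t += a.shape[0]
    stack = np.concatenate(arrays, axis=0)
    within = [np.abs(np.diff(a, axis=0)).mean(axis=(1, 2)) for a in arrays if a.shape[0] > 1]
    threshold = float(np.percentile(np.concatenate(within), 99.0)) if within else None
    gaps = [float(np.abs(arrays[i + 1][0] - arrays[i][-1]).mean())
            for i in range(len(arrays) - 1)]
    return stack, SessionIndex(session_ids=ids, bounds=bounds,
                               junction_gaps=gaps, junction_threshold=threshold)
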