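"""Synthetic multi-session one-photon Ca2+ video generator with exact ground truth.

The generative model mirrors what real miniscope recordings look like:
blob-shaped neuronal footprints placed with minimum-separation constraints,
Bernoulli transient onsets convolved with a double-exponential kernel,
per-neuron rates/kinetics drawn from lognormal distributions, a static
vessel-bearing baseline, spatially smoothed background fluctuations,
weakly correlated noise, and smooth non-rigid inter-session misalignment
built from gradients of a random Gaussian field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import SimulationConfig

__all__ = [
    "GroundTruth",
    "sample_footprints",
    "sample_traces",
    "synth_vessel_baseline",
    "blend_fovs",
    "sample_misalignment_field",
    "render_sessions",
]


@dataclass
class GroundTruth:
    """Simulator truth needed to score every downstream stage.

    ``footprints`` is K x (rows*cols) with unit-peak nonnegative rows;
    ``traces``/``events`` cover the full concatenated timeline (K x T_total)
    in pre-warp coordinates; ``misalignment_fields`` holds one (2, H, W)
    backward displacement field per session (session 0 is the reference and
    carries a zero field); ``amplitude_scale`` is 1 for normal activity,
    0.2 for sessions where a neuron's transients were damped, 0 when it
    was rendered inactive.
    """

    fov_shape: tuple[int, int]
    footprints: np.ndarray
    traces: np.ndarray
    events: np.ndarray
    centroids: np.ndarray
    baseline_per_session: list[np.ndarray]
    misalignment_fields: list[np.ndarray]
    activity_mask: np.ndarray
    amplitude_scale: np.ndarray
    vessel_mask: np.ndarray | None = None
    session_bounds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_neurons(self) -> int:
        return self.footprints.shape[0]

    def footprint_images(self) -> np.ndarray:
        return self.footprints.reshape((-1,) + tuple(self.fov_shape))


def _anisotropic_blob(shape: tuple[int, int], center: tuple[float, float],
                      radius: float, ecc: float, theta: float) -> np.ndarray:
    """Unit-peak anisotropic Gaussian blob truncated at 1% of peak."""
    h, w = shape
    cy, cx = center
    sig_major = radius / 2.0 * ecc
    sig_minor = radius / 2.0
    ext = int(np.ceil(3 * sig_major)) + 1
    y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = np.cos(theta) * dy + np.sin(theta) * dx
    v = -np.sin(theta) * dy + np.cos(theta) * dx
    g = np.exp(-0.5 * ((u / sig_major) ** 2 + (v / sig_minor) ** 2))
    g[g < 0.01] = 0.0
    if g.max() > 0:
        g = g / g.max()  # unit peak on the sampled grid
    out = np.zeros(shape)
    out[y0:y1, x0:x1] = g
    return out


def sample_footprints(config: SimulationConfig,
                      rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Place K blob footprints by rejection sampling with a minimum
    pairwise centroid separation (``min_separation_um`` / ``um_per_px``).

    Returns (footprints K x rows*cols, centroids K x 2 in px).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.fov_shape
    min_sep = config.min_separation_px
    margin = config.gsiz_px / 2.0
    centroids: list[np.ndarray] = []
    max_tries = 2000 * config.n_neurons
    tries = 0
    while len(centroids) < config.n_neurons:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {config.n_neurons} footprints with minimum "
                f"separation {min_sep:.1f} px in a {h}x{w} FOV: density limit reached")
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centroids):
            centroids.append(cand)
    cents = np.array(centroids)
    fps_list = []
    for cy, cx in cents:
        radius = config.gsiz_px * rng.uniform(0.8, 1.2)
        ecc = rng.uniform(1.0, 2.0)
        theta = rng.uniform(0, np.pi)
        fps_list.append(_anisotropic_blob((h, w), (cy, cx), radius, ecc, theta).ravel())
    return np.array(fps_list), cents


def calcium_kernel(taur: float, taud: float, fps: float, length: int | None = None) -> np.ndarray:
    """Double-exponential transient kernel g(t) = exp(-t/tau_d) - exp(-t/tau_r)
    sampled at t = k / fps. Zero at t=0, peaks at ln(tau_d/tau_r)/(1/tau_r - 1/tau_d)."""
    if taud <= taur:
        raise ValueError("decay constant must exceed rise constant")
    if length is None:
        length = int(np.ceil(10 * taud * fps)) + 1
    t = np.arange(length) / fps
    return np.exp(-t / taud) - np.exp(-t / taur)


def sample_traces(config: SimulationConfig, K: int, T: int,
                  rng: np.random.Generator | None = None,
                  session_bounds: list[tuple[int, int]] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Draw per-neuron kinetics and event trains; build traces by convolution.

    Per neuron the transient probability p and the inverse time constants
    1/tau_r, 1/tau_d are lognormal draws; pairs violating tau_d > tau_r are
    resampled. Event trains are Bernoulli(p) per frame, resampled until each
    session window contains at least one event. Traces are the events
    convolved with the double-exponential kernel (unit kernel scale).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if session_bounds is None:
        session_bounds = [(0, T)]
    p = np.exp(rng.normal(config.rate_logmu, config.rate_logsigma, size=K))
    p = np.clip(p, 1.0 / max(b - a for a, b in session_bounds), 0.5)
    taur = np.empty(K)
    taud = np.empty(K)
    for k in range(K):
        for attempt in range(1000):
            tr = 1.0 / np.exp(rng.normal(config.taur_inv_logmu, config.taur_inv_logsigma))
            td = 1.0 / np.exp(rng.normal(config.taud_inv_logmu, config.taud_inv_logsigma))
            if td > tr:
                taur[k], taud[k] = tr, td
                break
        else:
            raise RuntimeError("could not sample tau_d > tau_r within resampling budget")
    events = np.zeros((K, T), dtype=bool)
    for k in range(K):
        for (a, b) in session_bounds:
            n = b - a
            for attempt in range(10000):
                ev = rng.random(n) < p[k]
                if ev.any():
                    events[k, a:b] = ev
                    break
            else:  # pragma: no cover - p is floored above
                events[k, a + rng.integers(n)] = True
    traces = np.zeros((K, T))
    for k in range(K):
        ker = calcium_kernel(taur[k], taud[k], config.fps, length=T)
        traces[k] = np.convolve(events[k].astype(float), ker)[:T]
    kinetics = {"p": p, "tau_r": taur, "tau_d": taud}
    return traces, events, kinetics


def _random_walk_vessel(mask: np.ndarray, rng: np.random.Generator,
                        width: float, n_steps: int) -> None:
    """Rasterize one meandering vessel branch into ``mask`` (in place)."""
    h, w = mask.shape
    y = rng.uniform(0, h)
    x = rng.uniform(0, w)
    theta = rng.uniform(0, 2 * np.pi)
    r = width / 2.0
    for _ in range(n_steps):
        theta += rng.normal(0, 0.25)
        y += np.sin(theta) * 1.0
        x += np.cos(theta) * 1.0
        if not (-width <= y < h + width and -width <= x < w + width):
            break
        y0, y1 = int(max(0, y - r - 1)), int(min(h, y + r + 2))
        x0, x1 = int(max(0, x - r - 1)), int(min(w, x + r + 2))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2


def synth_vessel_baseline(config: SimulationConfig,
                          rng: np.random.Generator | None = None,
                          return_mask: bool = False):
    """Procedural static baseline: a smooth bright background crossed by
    dark branching vessel trees (random walks with widths spanning the
    diameter range the Hessian filter targets). Intensities in [0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.fov_shape
    # smooth bright background: low-frequency Gaussian random field
    bg = ndimage.gaussian_filter(rng.normal(size=(h, w)), sigma=max(h, w) / 6.0)
    span = np.ptp(bg)
    if span > 0:
        bg = (bg - bg.min()) / span
    img = 0.6 + 0.3 * bg
    vessel_mask = np.zeros((h, w), dtype=bool)
    n_steps = int(2.0 * max(h, w))
    for b in range(config.n_vessel_branches):
        width = rng.uniform(3.0, 9.0)
        _random_walk_vessel(vessel_mask, rng, width, n_steps)
        # occasional side branch from a random vessel pixel
        if b % 3 == 0 and vessel_mask.any():
            _random_walk_vessel(vessel_mask, rng, width * 0.6, n_steps // 2)
    depth = ndimage.gaussian_filter(vessel_mask.astype(float), sigma=1.0)
    img = img * (1.0 - 0.55 * depth)
    img = np.clip(img, 0.0, 1.0)
    if return_mask:
        return img, vessel_mask
    return img


def blend_fovs(image_a: np.ndarray, image_b: np.ndarray, w: float) -> np.ndarray:
    """Convex combination image_a * w + image_b * (1 - w)."""
    if image_a.shape != image_b.shape:
        raise ValueError("blend_fovs requires images of identical shape")
    if not 0.0 <= w <= 1.0:
        raise ValueError("blend weight must lie in [0, 1]")
    return image_a * w + image_b * (1.0 - w)


def gradient_gaussian_field(shape: tuple[int, int], sigma: float,
                            amplitude_px: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Smooth random displacement field: the spatial gradient of white noise
    smoothed by a Gaussian of ``sigma``, rescaled so the maximum displacement
    magnitude equals ``amplitude_px``. Returns a (2, rows, cols) array
    ordered (dy, dx); being the gradient of a smooth scalar, each component
    is itself smooth.
    """
    if amplitude_px < 0:
        raise ValueError("amplitude must be >= 0")
    scalar = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma,
                                     mode="reflect")
    dy, dx = np.gradient(scalar)
    field = np.stack([dy, dx])
    if amplitude_px == 0:
        return np.zeros_like(field)
    peak = np.hypot(field[0], field[1]).max()
    if peak == 0:
        return np.zeros_like(field)
    return field * (amplitude_px / peak)


def sample_misalignment_field(config: SimulationConfig,
                              rng: np.random.Generator | None = None,
                              amplitude_px: float | None = None) -> np.ndarray:
    """Per-session misalignment field (see :func:`gradient_gaussian_field`)
    with the configured smoothing sigma and amplitude."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if amplitude_px is None:
        amplitude_px = config.misalign_amplitude_px
    return gradient_gaussian_field(tuple(config.fov_shape), config.misalign_sigma,
                                   amplitude_px, rng)


def _warp_frame(frame: np.ndarray, disp: np.ndarray) -> np.ndarray:
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(frame, [yy + disp[0], xx + disp[1]],
                                   order=1, mode="nearest")


def render_sessions(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[np.ndarray], GroundTruth]:
    """Render per-session video stacks plus the GroundTruth record.

    Each frame is baseline + signal + background + correlated noise, then
    warped by the session's misalignment field. Transient amplitudes are
    scaled so the peak trace value over noise sigma equals ``config.pnr``.
    Remapped neurons are silenced in one randomly chosen session;
    SNR-dropped neurons keep their events but at 20% amplitude.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.fov_shape
    K, S, Tses = config.n_neurons, config.n_sessions, config.frames_per_session
    T_total = S * Tses
    bounds = [(s * Tses, (s + 1) * Tses) for s in range(S)]

    A, centroids = sample_footprints(config, rng)
    traces, events, kinetics = sample_traces(config, K, T_total, rng, bounds)

    # activity / amplitude bookkeeping
    activity = np.ones((K, S), dtype=bool)
    scale = np.ones((K, S))
    n_remap = int(np.floor(K * config.remap_fraction))
    remap_idx = rng.choice(K, size=n_remap, replace=False) if n_remap else np.array([], int)
    for k in remap_idx:
        s_off = int(rng.integers(S))
        activity[k, s_off] = False
        scale[k, s_off] = 0.0
    eligible = np.setdiff1d(np.arange(K), remap_idx)
    n_drop = int(np.floor(K * config.snr_drop_fraction))
    drop_idx = rng.choice(eligible, size=min(n_drop, eligible.size), replace=False) \
        if n_drop else np.array([], int)
    for k in drop_idx:
        s_low = int(rng.integers(S))
        scale[k, s_low] = 0.2

    # per-neuron amplitude so that peak transient / noise sigma == pnr
    # (noise sigma is 1 in model units)
    peaks = traces.max(axis=1)
    peaks[peaks == 0] = 1.0
    gain = config.pnr / peaks
    for s, (a, b) in enumerate(bounds):
        traces[:, a:b] *= (gain * scale[:, s])[:, None]
        events[:, a:b] &= activity[:, s][:, None]

    baseline_a, vessel_mask = synth_vessel_baseline(config, rng, return_mask=True)
    cfg_b = SimulationConfig(**{**config.__dict__, "seed": config.seed + 104729})
    baseline_b = synth_vessel_baseline(cfg_b, np.random.default_rng(cfg_b.seed))

    bg_spatial = ndimage.gaussian_filter(
        A.sum(axis=0).reshape(h, w), sigma=config.bg_sigma)
    if bg_spatial.max() > 0:
        bg_spatial = bg_spatial / bg_spatial.max()

    fields: list[np.ndarray] = []
    if config.misalign_progressive and S > 1:
        # gradual FOV drift: session fields accumulate random increments,
        # rescaled so the drift grows linearly to the configured amplitude
        # at the final session; neighbors stay within one step of each other
        acc = np.zeros((2, h, w))
        for s in range(S):
            if s == 0:
                fields.append(np.zeros((2, h, w)))
                continue
            acc = acc + sample_misalignment_field(config, rng, amplitude_px=1.0)
            mag = np.hypot(acc[0], acc[1]).max()
            target = config.misalign_amplitude_px * s / (S - 1)
            fields.append(acc * (target / mag) if mag > 0 else acc.copy())
    else:
        for s in range(S):
            fields.append(np.zeros((2, h, w)) if s == 0
                          else sample_misalignment_field(config, rng))
    baselines: list[np.ndarray] = []
    videos: list[np.ndarray] = []
    for s in range(S):
        disp = fields[s]
        if S > 1:
            w_s = 1.0 + (config.fov_blend_w - 1.0) * s / (S - 1)
        else:
            w_s = 1.0
        base = blend_fovs(baseline_a, baseline_b, w_s)
        baselines.append(base)
        a, b = bounds[s]
        sig = traces[:, a:b].T @ A  # T x P
        # slow multiplicative background fluctuation, std ~= noise sigma at peak
        walk = np.cumsum(rng.normal(0, 1.0, size=Tses))
        walk = ndimage.gaussian_filter1d(walk, sigma=max(2.0, config.fps))
        if walk.std() > 0:
            walk = (walk - walk.mean()) / walk.std()
        noise = rng.normal(size=(Tses, h, w))
        noise = ndimage.gaussian_filter(noise, sigma=(0, config.noise_corr_sigma,
                                                      config.noise_corr_sigma))
        nstd = noise.std()
        if nstd > 0:
            noise /= nstd
        frames = (10.0 * base[None, :, :]
                  + sig.reshape(Tses, h, w)
                  + walk[:, None, None] * bg_spatial[None, :, :]
                  + noise)
        if np.any(np.abs(disp) > 0):
            frames = np.stack([_warp_frame(f, disp) for f in frames])
        videos.append(np.clip(frames, 0.0, None))

    truth = GroundTruth(
        fov_shape=(h, w), footprints=A, traces=traces, events=events,
        centroids=centroids, baseline_per_session=baselines,
        misalignment_fields=fields, activity_mask=activity,
        amplitude_scale=scale, vessel_mask=vessel_mask, session_bounds=bounds)
    return videos, truth
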