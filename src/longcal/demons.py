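"""Diffeomorphic log-demons registration and displacement-field algebra.

Displacement fields are (2, H, W) arrays ordered (dy, dx) in pixels, with
0-based (row, col) coordinates and origin at the top-left. All warping is
backward: ``warped(x) = data(x + field(x))`` with bilinear interpolation
and replicate-edge padding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .config import DemonsConfig
from .vessels import enhance_vessels

__all__ = [
    "RegistrationDivergence",
    "warp",
    "compose_fields",
    "exp_field",
    "jacobian_determinant",
    "demons_force",
    "log_demons_register",
    "motion_correct_session",
]

log = logging.getLogger(__name__)


class RegistrationDivergence(RuntimeError):
    """Raised when the demons energy grows for several consecutive iterations."""

    def __init__(self, message: str, energies: list[float]):
        super().__init__(message)
        self.energies = energies


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return yy.astype(float), xx.astype(float)


def warp(data: np.ndarray, field: np.ndarray, mode: str = "bilinear") -> np.ndarray:
    """Backward-warp an image (H, W) or video (T, H, W) by a displacement field.

    ``mode='nearest'`` selects nearest-neighbor sampling for label images.
    """
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("displacement field contains non-finite values")
    data = np.asarray(data)
    spatial = data.shape[-2:]
    if field.shape != (2,) + spatial:
        raise ValueError("field shape does not match data spatial dimensions")
    order = 0 if mode == "nearest" else 1
    yy, xx = _grid(spatial)
    coords = [yy + field[0], xx + field[1]]
    if data.ndim == 2:
        return ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    if data.ndim == 3:
        return np.stack([
            ndimage.map_coordinates(frame, coords, order=order, mode="nearest")
            for frame in data
        ])
    raise ValueError("data must be a 2-D image or 3-D video")


def compose_fields(f_outer: np.ndarray, f_inner: np.ndarray) -> np.ndarray:
    """Compose backward displacement fields so that

        warp(x, compose_fields(a, b)) == warp(warp(x, b), a)

    i.e. ``b`` acts on the image first. Pointwise:
    result(x) = a(x) + b(x + a(x)).
    """
    f_outer = np.asarray(f_outer, dtype=float)
    f_inner = np.asarray(f_inner, dtype=float)
    if f_outer.shape != f_inner.shape:
        raise ValueError("fields must share shape to compose")
    yy, xx = _grid(f_outer.shape[1:])
    coords = [yy + f_outer[0], xx + f_outer[1]]
    warped_inner = np.stack([
        ndimage.map_coordinates(f_inner[c], coords, order=1, mode="nearest")
        for c in range(2)
    ])
    return f_outer + warped_inner


def exp_field(v: np.ndarray, max_step: float = 0.5) -> np.ndarray:
    """Exponential map of a stationary velocity field by scaling and squaring.

    N is chosen so the scaled step max |v| / 2^N stays below ``max_step`` px,
    which keeps each elementary displacement trivially diffeomorphic.
    """
    v = np.asarray(v, dtype=float)
    mag = np.hypot(v[0], v[1]).max()
    if mag == 0:
        return v.copy()
    n = max(0, int(np.ceil(np.log2(mag / max_step))))
    u = v / (2 ** n)
    for _ in range(n):
        u = compose_fields(u, u)
    return u


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Jacobian determinant of the map x -> x + field(x), per pixel."""
    dy_dy = np.gradient(field[0], axis=0)
    dy_dx = np.gradient(field[0], axis=1)
    dx_dy = np.gradient(field[1], axis=0)
    dx_dx = np.gradient(field[1], axis=1)
    return (1.0 + dy_dy) * (1.0 + dx_dx) - dy_dx * dx_dy


def is_diffeomorphic(field: np.ndarray) -> bool:
    """True when the Jacobian determinant is positive at every interior pixel."""
    det = jacobian_determinant(field)
    return bool(np.all(det[1:-1, 1:-1] > 0))


def demons_force(F: np.ndarray, M_warped: np.ndarray,
                 sigma_x2: float = 1.0, sigma_i2: float = 1.0) -> np.ndarray:
    """Additive demons force

        v = (F - M) grad(M) / (|grad M|^2 + (sigma_i^2/sigma_x^2)(F - M)^2)

    evaluated per pixel on the current warped moving image; pixels where the
    denominator vanishes (flat and matched) get zero force.
    """
    F = np.asarray(F, dtype=float)
    M_warped = np.asarray(M_warped, dtype=float)
    if F.shape != M_warped.shape:
        raise ValueError("fixed and moving images must share shape")
    diff = F - M_warped
    gy, gx = np.gradient(M_warped)
    denom = gy * gy + gx * gx + (sigma_i2 / sigma_x2) * diff * diff
    with np.errstate(invalid="ignore", divide="ignore"):
        vy = np.where(denom > 0, diff * gy / denom, 0.0)
        vx = np.where(denom > 0, diff * gx / denom, 0.0)
    return np.stack([vy, vx])


def _normalize01(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    span = np.ptp(img)
    if span == 0:
        return np.zeros_like(img)
    return (img - img.min()) / span


def log_demons_register(F: np.ndarray, M: np.ndarray,
                        config: DemonsConfig | None = None,
                        level: int = -1,
                        init_field: np.ndarray | None = None,
                        return_energies: bool = False):
    """Single-level diffeomorphic log-demons registration of M onto F.

    Per iteration: warp M by the running field S; compute the additive
    demons force; fluid-regularize (Gaussian-smooth the velocity); compose
    S with exp(v); diffusion-regularize (Gaussian-smooth S). Stops at
    ``max_iters`` for the level or when the relative energy change drops
    below ``tol``. Raises :class:`RegistrationDivergence` after five
    consecutive energy increases.
    """
    if config is None:
        config = DemonsConfig()
    config.validate()
    F = _normalize01(F)
    M = _normalize01(M)
    if F.shape != M.shape:
        raise ValueError("images must share shape")
    s_fluid = config.sigma_fluid[level]
    s_diff = config.sigma_diffusion[level]
    s_x2 = config.sigma_x2[level]
    s_i2 = config.sigma_i2[level]
    iters = config.max_iters[level]

    S = np.zeros((2,) + F.shape) if init_field is None else np.asarray(init_field, float).copy()
    energies: list[float] = []
    best_S, best_E = S.copy(), np.inf
    n_grow = 0
    for it in range(iters):
        Mw = warp(M, S)
        v = demons_force(F, Mw, sigma_x2=s_x2, sigma_i2=s_i2)
        if s_fluid > 0:
            v = np.stack([ndimage.gaussian_filter(v[c], s_fluid, mode="nearest")
                          for c in range(2)])
        S = compose_fields(exp_field(v), S)
        if s_diff > 0:
            S = np.stack([ndimage.gaussian_filter(S[c], s_diff, mode="nearest")
                          for c in range(2)])
        E = float(np.mean((F - warp(M, S)) ** 2))
        energies.append(E)
        if E < best_E:
            best_S, best_E = S.copy(), E
        # sub-1% blips around the minimum are tolerated; sustained growth is not
        if E > best_E * 1.01:
            n_grow += 1
            if n_grow >= 5:
                if best_E < energies[0]:
                    break  # oscillation around an improved minimum: converged
                raise RegistrationDivergence(
                    f"demons energy grew for {n_grow} consecutive iterations "
                    f"at iteration {it}", energies)
        else:
            n_grow = 0
        if len(energies) >= 2:
            prev = energies[-2]
            if prev > 0 and abs(prev - E) / prev < config.tol:
                break
    S = best_S
    if not is_diffeomorphic(S):
        # a final diffusion pass restores smoothness in pathological cases
        S = np.stack([ndimage.gaussian_filter(S[c], max(s_diff, 1.0), mode="nearest")
                      for c in range(2)])
        if not is_diffeomorphic(S):
            raise RegistrationDivergence("registration produced a folding field",
                                         energies)
    if return_energies:
        return S, energies
    return S


@dataclass
class MotionCorrection:
    video: np.ndarray
    fields: list[np.ndarray] = dc_field(default_factory=list)
    template: np.ndarray | None = None


def motion_correct_session(video: np.ndarray,
                           config: DemonsConfig | None = None,
                           level: int = -1) -> MotionCorrection:
    """Within-session motion correction against a vessel-enhanced template.

    The template is the vessel-enhanced median frame; each frame's
    vessel-enhanced image is registered to it and the raw frame warped by
    the resulting field. A frame whose registration diverges keeps the
    identity field (with a warning).
    """
    video = np.asarray(video, dtype=float)
    if video.ndim != 3 or video.shape[0] < 1:
        raise ValueError("expected a (T, H, W) video with T >= 1")
    template = enhance_vessels(np.median(video, axis=0)).values
    corrected = np.empty_like(video)
    fields: list[np.ndarray] = []
    for t, frame in enumerate(video):
        moving = enhance_vessels(frame).values
        try:
            S = log_demons_register(template, moving, config, level=level)
        except RegistrationDivergence:
            log.warning("frame %d registration diverged; keeping identity field", t)
            S = np.zeros((2,) + frame.shape)
        fields.append(S)
        corrected[t] = warp(frame, S)
    return MotionCorrection(video=corrected, fields=fields, template=template)
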