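"""Configuration dataclasses for every pipeline stage, with YAML round-trip.

All spatial quantities are in pixels unless the field name says otherwise
(``*_um`` fields are micrometres and convert through ``um_per_px``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "SimulationConfig",
    "VesselFilterConfig",
    "DemonsConfig",
    "ExtractionConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


@dataclass
class SimulationConfig:
    """Generative model for multi-session one-photon Ca2+ videos.

    The defaults encode the study conditions used throughout the test
    suite: per-neuron transient probability and kinetic rates drawn from
    lognormal distributions fitted to dentate-gyrus recordings, a constant
    peak-to-noise ratio of 2, spatially smoothed background (sigma 20 px),
    weakly correlated noise (sigma 0.5 px) and inter-session misalignment
    built from gradients of a sigma-60 random Gaussian field.
    """

    fov_shape: tuple[int, int] = (128, 160)
    n_neurons: int = 50
    min_separation_um: float = 26.0  # presets: 26 (low), 21 (medium), 8 (high overlap)
    um_per_px: float = 2.0
    frames_per_session: int = 1000
    fps: float = 10.0
    n_sessions: int = 2
    # lognormal parameters (mu, sigma of log) for per-frame transient prob p
    rate_logmu: float = -4.9
    rate_logsigma: float = 2.25
    # lognormal parameters for 1/tau_r and 1/tau_d (units 1/s)
    taur_inv_logmu: float = 2.08
    taur_inv_logsigma: float = 0.29
    taud_inv_logmu: float = 0.55
    taud_inv_logsigma: float = 0.44
    pnr: float = 2.0
    bg_sigma: float = 20.0
    noise_corr_sigma: float = 0.5
    misalign_sigma: float = 60.0
    misalign_amplitude_um: float = 8.0  # presets ~8 and ~12.5
    misalign_progressive: bool = False  # accumulate drift across sessions
    fov_blend_w: float = 1.0
    remap_fraction: float = 0.0
    snr_drop_fraction: float = 0.0
    # footprint geometry
    gsiz_px: float = 6.0  # approximate neuron diameter in pixels
    n_vessel_branches: int = 12
    seed: int = 0

    @property
    def min_separation_px(self) -> float:
        return self.min_separation_um / self.um_per_px

    @property
    def misalign_amplitude_px(self) -> float:
        return self.misalign_amplitude_um / self.um_per_px

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for name in ("rate_logsigma", "taur_inv_logsigma", "taud_inv_logsigma",
                     "bg_sigma", "noise_corr_sigma", "misalign_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.fov_blend_w <= 1.0:
            raise ValueError("fov_blend_w must lie in [0, 1]")
        if self.pnr <= 0:
            raise ValueError("pnr must be > 0")
        diag = (self.fov_shape[0] ** 2 + self.fov_shape[1] ** 2) ** 0.5
        if self.min_separation_px >= diag:
            raise ValueError("min separation exceeds FOV diagonal")


@dataclass
class VesselFilterConfig:
    """Multiscale Hessian ridge filter for dark, elongated vessel structures.

    Vessel diameters d_i are linearly spaced over ``scale_range``·gSiz and
    each scale is smoothed with sigma_i = d_i / 4.
    """

    gSiz: float = 10.0
    n_scales: int = 10
    scale_range: tuple[float, float] = (2.4, 3.5)

    def sigmas(self) -> list[float]:
        lo, hi = self.scale_range
        if not lo < hi:
            raise ValueError("scale_range must be increasing")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.n_scales == 1:
            diameters = [lo * self.gSiz]
        else:
            step = (hi - lo) / (self.n_scales - 1)
            diameters = [(lo + i * step) * self.gSiz for i in range(self.n_scales)]
        sig = [d / 4.0 for d in diameters]
        if any(s <= 0 for s in sig):
            raise ValueError("all filter sigmas must be > 0")
        return sig


@dataclass
class DemonsConfig:
    """Per-pyramid-level parameters for diffeomorphic log-demons registration.

    Vectors are indexed coarse-to-fine; their common length defines the
    number of pyramid levels.
    """

    sigma_fluid: tuple[float, ...] = (1.0, 1.0, 3.0, 3.0)
    sigma_diffusion: tuple[float, ...] = (5.0, 5.0, 3.0, 3.0)
    sigma_x2: tuple[float, ...] = (1.0, 1.0, 1.0, 2.0)
    sigma_i2: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    max_iters: tuple[int, ...] = (60, 60, 60, 60)
    tol: float = 1e-4

    @property
    def n_levels(self) -> int:
        return len(self.sigma_fluid)

    def validate(self) -> None:
        n = self.n_levels
        for name in ("sigma_diffusion", "sigma_x2", "sigma_i2", "max_iters"):
            if len(getattr(self, name)) != n:
                raise ValueError("per-level parameter vectors must share one length")
        if any(s < 0 for s in self.sigma_fluid + self.sigma_diffusion):
            raise ValueError("sigmas must be >= 0")


@dataclass
class ExtractionConfig:
    """Seeded nonnegative factorization parameters (CNMF-E conventions)."""

    gSig: float = 2.5
    gSiz: float | None = None  # defaults to 4 * gSig
    min_corr: float = 0.15
    min_pnr: float = 2.5
    ring_radius: float | None = None  # defaults to round(1.5 * gSiz)
    batch_frames: int = 3000
    merge_corr_threshold: float = 0.65
    max_components: int = 1000
    n_patches: int = 12
    n_iters: int = 3
    seed: int = 0

    def resolved_gsiz(self) -> float:
        return self.gSiz if self.gSiz is not None else 4.0 * self.gSig

    def resolved_ring_radius(self) -> float:
        if self.ring_radius is not None:
            return self.ring_radius
        return round(1.5 * self.resolved_gsiz())

    def validate(self) -> None:
        if not 0.0 < self.min_corr < 1.0:
            raise ValueError("min_corr must lie in (0, 1)")
        if self.min_pnr <= 0:
            raise ValueError("min_pnr must be > 0")
        if self.batch_frames < 2:
            raise ValueError("batch_frames must be >= 2")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: nested stage configs plus paths."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    vessel: VesselFilterConfig = field(default_factory=VesselFilterConfig)
    demons: DemonsConfig = field(default_factory=DemonsConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    session_paths: list[str] = field(default_factory=list)
    out_dir: str = "longcal_out"
    seed: int = 0
    bv_threshold: float = 2.7
    tau: float = 0.8
    downsample_factor: int = 1
    motion_correct: bool = False
    log_level: str = "INFO"


_NESTED = {
    "simulation": SimulationConfig,
    "vessel": VesselFilterConfig,
    "demons": DemonsConfig,
    "extraction": ExtractionConfig,
}


def _from_mapping(cls: type, data: dict[str, Any]) -> Any:
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise KeyError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if cls is PipelineConfig and key in _NESTED and isinstance(value, dict):
            value = _from_mapping(_NESTED[key], value)
        elif isinstance(value, list) and _is_tuple_field(names[key]):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _is_tuple_field(f: dataclasses.Field) -> bool:
    return "tuple" in str(f.type)


def _to_mapping(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_mapping(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def load_config(path: str, cls: type = PipelineConfig) -> Any:
    """Load a config dataclass from YAML, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_mapping(cls, data)


def save_config(cfg: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_mapping(cfg), fh, sort_keys=False)
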