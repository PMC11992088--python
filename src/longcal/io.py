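"""Reading and writing video stacks, ground truth, and component sets.

HDF5 is the internal interchange format; TIFF is accepted and produced at
the edges of the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .extract import ComponentSet
from .simulate import GroundTruth

__all__ = [
    "read_stack",
    "write_stack",
    "save_ground_truth",
    "load_ground_truth",
    "save_components",
    "load_components",
]

_H5_VIDEO_KEY = "video"


def read_stack(path: str | Path, fps: float | None = None
               ) -> tuple[np.ndarray, dict]:
    """Read a (T, H, W) stack from multi-page TIFF or HDF5.

    Returns (array, metadata). Raises a ValueError naming the expected
    format for anything that is not a readable 3-D stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {"fps": fps}
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if _H5_VIDEO_KEY not in f:
                raise ValueError(
                    f"{path}: expected an HDF5 file with a 3-D '{_H5_VIDEO_KEY}' dataset")
            ds = f[_H5_VIDEO_KEY]
            if ds.ndim != 3:
                raise ValueError(f"{path}: dataset must be 3-D (T, H, W), got {ds.ndim}-D")
            data = ds[:]
            if "fps" in ds.attrs and fps is None:
                meta["fps"] = float(ds.attrs["fps"])
    else:
        try:
            data = tifffile.imread(str(path))
        except Exception as exc:
            raise ValueError(
                f"{path}: expected a multi-page TIFF or HDF5 stack ({exc})") from exc
        if data.ndim == 2:
            raise ValueError(f"{path}: single-page image; a 3-D (T, H, W) "
                             f"multi-page TIFF stack is required")
        if data.ndim != 3:
            raise ValueError(f"{path}: not a readable 3-D multi-page TIFF or "
                             f"HDF5 stack (parsed as {data.ndim}-D)")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: stack contains non-finite values")
    return data, meta


def write_stack(path: str | Path, video: np.ndarray, fps: float = 10.0) -> None:
    path = Path(path)
    video = np.asarray(video)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(_H5_VIDEO_KEY, data=video)
            ds.attrs["fps"] = fps
    else:
        tifffile.imwrite(str(path), video.astype(np.float32))


def save_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fov_shape"] = truth.fov_shape
        f["footprints"] = truth.footprints
        f["traces"] = truth.traces
        f["events"] = truth.events.astype(np.uint8)
        f["centroids"] = truth.centroids
        f["activity_mask"] = truth.activity_mask.astype(np.uint8)
        f["amplitude_scale"] = truth.amplitude_scale
        f["session_bounds"] = np.array(truth.session_bounds)
        for s, (base, disp) in enumerate(zip(truth.baseline_per_session,
                                             truth.misalignment_fields)):
            f[f"baseline/{s}"] = base
            ds = f.create_dataset(f"misalignment/{s}", data=disp)
            ds.attrs["layout"] = "(2, rows, cols): (dy, dx) in px"
        if truth.vessel_mask is not None:
            f["vessel_mask"] = truth.vessel_mask.astype(np.uint8)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        n_sessions = len(f["baseline"])
        return GroundTruth(
            fov_shape=tuple(int(v) for v in f.attrs["fov_shape"]),
            footprints=f["footprints"][:],
            traces=f["traces"][:],
            events=f["events"][:].astype(bool),
            centroids=f["centroids"][:],
            baseline_per_session=[f[f"baseline/{s}"][:] for s in range(n_sessions)],
            misalignment_fields=[f[f"misalignment/{s}"][:] for s in range(n_sessions)],
            activity_mask=f["activity_mask"][:].astype(bool),
            amplitude_scale=f["amplitude_scale"][:],
            vessel_mask=f["vessel_mask"][:].astype(bool) if "vessel_mask" in f else None,
            session_bounds=[tuple(map(int, b)) for b in f["session_bounds"][:]],
        )


def save_components(path: str | Path, comps: ComponentSet,
                    session_bounds: list[tuple[int, int]] | None = None) -> None:
    """Persist a component set; footprints stored as sparse COO triplets."""
    with h5py.File(path, "w") as f:
        f.attrs["fov_shape"] = comps.fov_shape
        f.attrs["n_components"] = comps.n_components
        rows, cols = np.nonzero(comps.A)
        f["A_coo/row"] = rows
        f["A_coo/col"] = cols
        f["A_coo/val"] = comps.A[rows, cols]
        f["C"] = comps.C
        f["S"] = comps.S
        f["W"] = comps.W
        f["B0"] = comps.B0
        if session_bounds is not None:
            f["session_index"] = np.array(session_bounds)


def load_components(path: str | Path) -> ComponentSet:
    with h5py.File(path, "r") as f:
        shape = tuple(int(v) for v in f.attrs["fov_shape"])
        K = int(f.attrs["n_components"])
        A = np.zeros((K, shape[0] * shape[1]))
        A[f["A_coo/row"][:], f["A_coo/col"][:]] = f["A_coo/val"][:]
        return ComponentSet(A=A, C=f["C"][:], S=f["S"][:], W=f["W"][:],
                            B0=f["B0"][:], fov_shape=shape)


def save_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
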