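"""Domain types and NIfTI / sidecar I/O shared by every pipeline stage.

Unit conventions used throughout the package:

* relaxation times in milliseconds (ms),
* relaxation rates in s⁻¹ (``rate = 1000 / time_ms``),
* H₂¹⁷O concentrations in mole-percent of water molecules,
* voxel sizes in mm, series durations in minutes.

Volumes are NIfTI-1 files read and written with :mod:`nibabel`; acquisition
protocols travel as small YAML sidecars (keys ``sequence_kind``, ``tr_ms``,
``echo_times_ms``, ``flip_angles_deg``, ``voxel_size_mm``,
``series_duration_min``).  The frame axis (echo, flip angle, or dynamic
timepoint) is always the 4th NIfTI dimension, in sidecar list order.

Voxels where a fit failed carry NaN in the time/rate/amplitude maps; the
boolean ``converged_mask`` is the authoritative record of validity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "SequenceKind",
    "FrameAxis",
    "AcquisitionProtocol",
    "ImageSeries",
    "ParametricMap",
    "GroundTruthMaps",
    "ValidationError",
    "ProtocolError",
    "ProtocolMismatchError",
    "GridMismatchError",
    "EmptyMaskError",
    "load_image_series",
    "save_image_series",
    "load_mask",
    "save_mask",
    "save_parametric_map",
    "load_parametric_map",
    "read_sidecar",
    "write_sidecar",
    "time_to_rate",
    "rate_to_time",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class ValidationError(ValueError):
    """An input violates a documented contract."""


class ProtocolError(ValidationError):
    """A protocol is unusable for the requested operation."""


class ProtocolMismatchError(ProtocolError):
    """Image geometry or frame count disagrees with the sidecar protocol."""


class GridMismatchError(ValidationError):
    """Two volumes do not share the same spatial grid."""


class EmptyMaskError(ValidationError):
    """A mask selects no voxels."""


# --------------------------------------------------------------------------
# Unit helpers
# --------------------------------------------------------------------------

def time_to_rate(time_ms):
    """Convert a relaxation time in ms to a rate in s⁻¹ (NaN-preserving)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1000.0 / np.asarray(time_ms, dtype=float)


def rate_to_time(rate_per_s):
    """Convert a relaxation rate in s⁻¹ to a time in ms (NaN-preserving)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1000.0 / np.asarray(rate_per_s, dtype=float)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class SequenceKind(str, enum.Enum):
    VFA_SPGR = "vfa_spgr"
    MULTIECHO_GRE = "multiecho_gre"
    MULTIECHO_TSE = "multiecho_tse"


class FrameAxis(str, enum.Enum):
    ECHO = "echo"
    FLIP_ANGLE = "flip_angle"
    DYNAMIC = "dynamic"


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Sequence timing and geometry metadata driving simulation and fitting.

    Parameters
    ----------
    sequence_kind:
        One of the three acquisition families: spoiled gradient echo with
        variable flip angle (T1), multi-echo gradient echo (T2*), or
        multi-echo turbo spin echo (T2).
    tr_ms:
        Repetition time in ms.
    echo_times_ms:
        Strictly increasing echo times in ms; empty for VFA.
    flip_angles_deg:
        Strictly increasing flip angles in (0°, 90°]; empty for multi-echo.
    voxel_size_mm:
        (dx, dy, dz) voxel size in mm.
    matrix_shape:
        Spatial matrix (nx, ny, nz).
    series_duration_min:
        Duration of one dynamic series in minutes; only meaningful for
        dynamic acquisitions.
    """

    sequence_kind: SequenceKind
    tr_ms: float
    echo_times_ms: tuple[float, ...] = ()
    flip_angles_deg: tuple[float, ...] = ()
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    matrix_shape: tuple[int, int, int] = (1, 1, 1)
    series_duration_min: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence_kind", SequenceKind(self.sequence_kind))
        object.__setattr__(self, "echo_times_ms", tuple(float(t) for t in self.echo_times_ms))
        object.__setattr__(self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "matrix_shape", tuple(int(n) for n in self.matrix_shape))
        if self.tr_ms <= 0:
            raise ValidationError(f"tr_ms must be positive, got {self.tr_ms}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError(f"voxel_size_mm must be 3 positive values, got {self.voxel_size_mm}")
        if len(self.matrix_shape) != 3 or any(n <= 0 for n in self.matrix_shape):
            raise ValidationError(f"matrix_shape must be 3 positive integers, got {self.matrix_shape}")
        has_echoes = len(self.echo_times_ms) > 0
        has_angles = len(self.flip_angles_deg) > 0
        if has_echoes == has_angles:
            raise ValidationError(
                "exactly one of echo_times_ms / flip_angles_deg must be non-empty "
                f"(got {len(self.echo_times_ms)} echoes, {len(self.flip_angles_deg)} angles)"
            )
        if has_echoes:
            te = np.asarray(self.echo_times_ms)
            if te[0] <= 0 or np.any(np.diff(te) <= 0):
                raise ValidationError(f"echo_times_ms must be strictly increasing and positive: {self.echo_times_ms}")
            if self.tr_ms <= te[-1]:
                raise ValidationError(
                    f"tr_ms ({self.tr_ms}) must exceed the longest echo time ({te[-1]})"
                )
            if self.sequence_kind is SequenceKind.VFA_SPGR:
                raise ValidationError("vfa_spgr protocols take flip angles, not echo times")
        else:
            fa = np.asarray(self.flip_angles_deg)
            if fa[0] <= 0 or fa[-1] > 90 or np.any(np.diff(fa) <= 0):
                raise ValidationError(
                    f"flip_angles_deg must be strictly increasing within (0, 90]: {self.flip_angles_deg}"
                )
            if self.sequence_kind is not SequenceKind.VFA_SPGR:
                raise ValidationError("multi-echo protocols take echo times, not flip angles")

    @property
    def n_frames(self) -> int:
        """Frames implied by the protocol lists (0 means dynamic/free)."""
        return max(len(self.echo_times_ms), len(self.flip_angles_deg))

    @property
    def frame_axis(self) -> FrameAxis:
        if self.sequence_kind is SequenceKind.VFA_SPGR:
            return FrameAxis.FLIP_ANGLE
        return FrameAxis.ECHO

    @property
    def in_plane_voxel_area_mm2(self) -> float:
        return self.voxel_size_mm[0] * self.voxel_size_mm[1]

    def affine(self) -> np.ndarray:
        """A diagonal NIfTI affine encoding the voxel size."""
        return np.diag([*self.voxel_size_mm, 1.0])


@dataclass
class ImageSeries:
    """A magnitude volume stack with the protocol that produced it.

    ``data`` has shape ``matrix_shape + (n_frames,)``; the 4th axis is the
    echo, flip-angle, or dynamic-time dimension depending on
    ``frame_axis_meaning``.
    """

    data: np.ndarray
    protocol: AcquisitionProtocol
    frame_axis_meaning: FrameAxis

    def __post_init__(self) -> None:
        self.frame_axis_meaning = FrameAxis(self.frame_axis_meaning)
        data = np.asarray(self.data, dtype=float)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise ValidationError(f"series data must be 3-D or 4-D, got ndim={data.ndim}")
        self.data = data
        if tuple(data.shape[:3]) != self.protocol.matrix_shape:
            raise ProtocolMismatchError(
                f"spatial shape {data.shape[:3]} does not match protocol matrix {self.protocol.matrix_shape}"
            )
        expected = self.protocol.n_frames
        if self.frame_axis_meaning is not FrameAxis.DYNAMIC and expected != data.shape[3]:
            raise ProtocolMismatchError(
                f"series has {data.shape[3]} frames but the protocol defines {expected}"
            )
        if np.any(data < 0):
            raise ValidationError("magnitude images must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class ParametricMap:
    """Per-voxel relaxation time/rate/amplitude with fit diagnostics.

    ``rate_map = 1000 / time_map`` on converged voxels (ms ↔ s⁻¹); voxels
    that were skipped or failed carry NaN with ``converged_mask`` False.
    """

    time_map: np.ndarray
    rate_map: np.ndarray
    amplitude_map: np.ndarray
    converged_mask: np.ndarray
    rss_map: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.time_map = np.asarray(self.time_map, dtype=float)
        self.rate_map = np.asarray(self.rate_map, dtype=float)
        self.amplitude_map = np.asarray(self.amplitude_map, dtype=float)
        self.rss_map = np.asarray(self.rss_map, dtype=float)
        self.converged_mask = np.asarray(self.converged_mask, dtype=bool)
        shapes = {a.shape for a in (self.time_map, self.rate_map, self.amplitude_map,
                                    self.rss_map, self.converged_mask)}
        if len(shapes) != 1:
            raise ValidationError(f"all component maps must share one grid, got shapes {shapes}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        ok = self.converged_mask
        if np.any(self.time_map[ok] <= 0):
            raise ValidationError("converged voxels must have positive relaxation times")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.time_map.shape

    def affine(self) -> np.ndarray:
        return np.diag([*self.voxel_size_mm, 1.0])


@dataclass
class GroundTruthMaps:
    """Simulation truth on the same grid as the rendered series."""

    true_t1: np.ndarray
    true_t2: np.ndarray
    true_t2star: np.ndarray
    true_amplitude: np.ndarray
    concentration_map: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("true_t1", "true_t2", "true_t2star", "true_amplitude", "concentration_map"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        obj = self.true_amplitude > 0
        if np.any(self.true_t2star[obj] > self.true_t2[obj] + 1e-9) or np.any(
            self.true_t2[obj] > self.true_t1[obj] + 1e-9
        ):
            raise ValidationError("ground truth must satisfy T2* <= T2 <= T1 inside objects")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.true_t2.shape


# --------------------------------------------------------------------------
# Sidecar I/O
# --------------------------------------------------------------------------

_SIDE_KEYS = ("sequence_kind", "tr_ms", "echo_times_ms", "flip_angles_deg",
              "voxel_size_mm", "series_duration_min")


def write_sidecar(protocol: AcquisitionProtocol, path) -> Path:
    """Write a protocol as a YAML sidecar; returns the path written."""
    path = Path(path)
    doc = {
        "sequence_kind": protocol.sequence_kind.value,
        "tr_ms": protocol.tr_ms,
        "echo_times_ms": list(protocol.echo_times_ms),
        "flip_angles_deg": list(protocol.flip_angles_deg),
        "voxel_size_mm": list(protocol.voxel_size_mm),
        "matrix_shape": list(protocol.matrix_shape),
        "series_duration_min": protocol.series_duration_min,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_sidecar(path, matrix_shape: Sequence[int] | None = None) -> AcquisitionProtocol:
    """Read a YAML protocol sidecar.

    ``matrix_shape`` overrides the sidecar's stored matrix (the NIfTI header
    is authoritative for geometry when loading a series).
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping) or "sequence_kind" not in doc:
        raise ValidationError(f"sidecar {path} is not a protocol document")
    shape = matrix_shape or doc.get("matrix_shape") or (1, 1, 1)
    return AcquisitionProtocol(
        sequence_kind=doc["sequence_kind"],
        tr_ms=float(doc["tr_ms"]),
        echo_times_ms=tuple(doc.get("echo_times_ms") or ()),
        flip_angles_deg=tuple(doc.get("flip_angles_deg") or ()),
        voxel_size_mm=tuple(doc.get("voxel_size_mm") or (1.0, 1.0, 1.0)),
        matrix_shape=tuple(shape),
        series_duration_min=doc.get("series_duration_min"),
    )


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def _load_nifti(path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, zooms


def load_image_series(path, sidecar) -> ImageSeries:
    """Load a 3-D/4-D NIfTI series together with its protocol sidecar.

    The frame count must match the sidecar's echo/flip-angle list (dynamic
    series accept any positive count) and the NIfTI voxel size must agree
    with the sidecar within 1%.
    """
    data, _, zooms = _load_nifti(path)
    if data.ndim not in (3, 4):
        raise ValidationError(f"expected a 3-D or 4-D NIfTI, got ndim={data.ndim}")
    if data.ndim == 3:
        data = data[..., np.newaxis]
    protocol = read_sidecar(sidecar, matrix_shape=data.shape[:3])
    if not np.allclose(zooms, protocol.voxel_size_mm, rtol=0.01):
        raise ProtocolMismatchError(
            f"NIfTI voxel size {zooms} disagrees with sidecar {protocol.voxel_size_mm}"
        )
    expected = protocol.n_frames
    meaning = protocol.frame_axis
    if protocol.series_duration_min is not None and expected != data.shape[3]:
        meaning = FrameAxis.DYNAMIC
    elif expected != data.shape[3]:
        raise ProtocolMismatchError(
            f"NIfTI has {data.shape[3]} frames but the sidecar defines {expected}"
        )
    if np.any(data < 0):
        raise ValidationError(f"{path}: magnitude series contains negative intensities")
    return ImageSeries(data=data, protocol=protocol, frame_axis_meaning=meaning)


def save_image_series(series: ImageSeries, path, sidecar=None) -> Path:
    """Write a series to NIfTI (and optionally its sidecar alongside)."""
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float64), series.protocol.affine())
    img.header.set_zooms((*series.protocol.voxel_size_mm, 1.0))
    nib.save(img, str(path))
    if sidecar is not None:
        write_sidecar(series.protocol, sidecar)
    return path


def load_mask(path, reference: ImageSeries | ParametricMap) -> np.ndarray:
    """Load a 0/1 NIfTI mask on the reference grid as a boolean volume."""
    data, _, _ = _load_nifti(path)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    ref_shape = reference.shape[:3] if isinstance(reference, ImageSeries) else reference.shape
    if tuple(data.shape) != tuple(ref_shape):
        raise GridMismatchError(
            f"mask grid {data.shape} does not match reference grid {tuple(ref_shape)}"
        )
    mask = data > 0.5
    if not mask.any():
        raise EmptyMaskError(f"mask {path} selects no voxels")
    return mask


def save_mask(mask: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.diag([*voxel_size_mm, 1.0]))
    nib.save(img, str(path))
    return path


_MAP_COMPONENTS = ("time", "rate", "amplitude", "rss")


def save_parametric_map(pmap: ParametricMap, out_dir, prefix: str = "map") -> dict[str, Path]:
    """Write a map bundle: ``<prefix>_{time,rate,amplitude,rss}.nii.gz`` as
    float volumes plus ``<prefix>_converged.nii.gz`` as 0/1 integers."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise IOError(f"output directory {out_dir} does not exist")
    affine = pmap.affine()
    paths: dict[str, Path] = {}
    arrays = {
        "time": pmap.time_map,
        "rate": pmap.rate_map,
        "amplitude": pmap.amplitude_map,
        "rss": pmap.rss_map,
    }
    for name, arr in arrays.items():
        p = out_dir / f"{prefix}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), str(p))
        paths[name] = p
    p = out_dir / f"{prefix}_converged.nii.gz"
    nib.save(nib.Nifti1Image(pmap.converged_mask.astype(np.uint8), affine), str(p))
    paths["converged"] = p
    return paths


def load_parametric_map(out_dir, prefix: str = "map") -> ParametricMap:
    """Read back a bundle written by :func:`save_parametric_map`."""
    out_dir = Path(out_dir)
    arrays = {}
    zooms = (1.0, 1.0, 1.0)
    for name in _MAP_COMPONENTS + ("converged",):
        data, _, zooms = _load_nifti(out_dir / f"{prefix}_{name}.nii.gz")
        arrays[name] = data
    return ParametricMap(
        time_map=arrays["time"],
        rate_map=arrays["rate"],
        amplitude_map=arrays["amplitude"],
        rss_map=arrays["rss"],
        converged_mask=arrays["converged"] > 0.5,
        voxel_size_mm=zooms,
    )
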