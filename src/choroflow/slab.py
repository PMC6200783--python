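"""En-face slab geometry for OCTA volumes.

OCT angiography devices export *en-face* slabs: 2-D images obtained by
aggregating the 3-D flow signal over a depth window anchored to a
segmented reference surface (here the outer retinal pigment epithelium,
RPE).  This module defines the volume/surface containers, the slab
specifications used for choroidal analysis (choriocapillaris and
half-choroid), the subfoveal choroidal thickness (SCT) measurement, and
the projection of a slab into an en-face image.

Conventions: arrays are 0-based and row-major, origin top-left; the
axial (depth) axis is the last array axis and increases posteriorly;
depths are expressed in micrometres below the volume's first sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "OCTAVolume",
    "SurfaceMap",
    "SlabSpec",
    "EnFaceImage",
    "CHORIOCAPILLARIS_SLAB",
    "DEVICE_DEFAULT_CC_SLAB",
    "HALF_CHOROID_WIDTH_UM",
    "SCT_ELIGIBILITY_CUTOFF_UM",
    "ThinChoroidWarning",
    "measure_sct",
    "half_choroid_spec",
    "resolve_slab",
    "project_slab",
]

#: Minimum subfoveal choroidal thickness (µm) for cohort eligibility;
#: thinner choroids are excluded to avoid pathologic-myopia eyes.
SCT_ELIGIBILITY_CUTOFF_UM = 150.0

#: Width (µm) of the half-choroid analysis slab.
HALF_CHOROID_WIDTH_UM = 30.0


class ThinChoroidWarning(UserWarning):
    """Raised when a half-choroid slab is requested for SCT below the
    eligibility cutoff; the slab is still produced."""


def _as_uint8(pixels: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating) or np.issubdtype(arr.dtype, np.integer):
            lo, hi = arr.min(initial=0), arr.max(initial=0)
            if lo < 0 or hi > 255:
                raise ValueError(f"{what}: intensities must lie in [0, 255], got [{lo}, {hi}]")
            arr = arr.astype(np.uint8)
        else:
            raise TypeError(f"{what}: unsupported dtype {arr.dtype}")
    return arr


@dataclass
class OCTAVolume:
    """A 3-D OCTA flow-signal volume.

    Parameters
    ----------
    flow : ndarray, shape (rows, cols, depth), uint8
        Flow-signal intensities; stationary tissue is dark, flow bright.
    axial_pitch_um : float
        Micrometres per axial (depth) sample.
    lateral_pitch_um : float
        Micrometres per lateral sample.
    field_size_mm : tuple of float, optional
        Lateral scan extent, e.g. ``(12.0, 12.0)`` for a wide-field scan.
    """

    flow: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float
    field_size_mm: Tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.flow = _as_uint8(self.flow, "OCTAVolume.flow")
        if self.flow.ndim != 3:
            raise ValueError(f"flow must be 3-D (rows, cols, depth), got shape {self.flow.shape}")
        if self.flow.shape[2] < 2:
            raise ValueError("volume needs at least 2 depth samples")
        if self.axial_pitch_um <= 0 or self.lateral_pitch_um <= 0:
            raise ValueError("axial_pitch_um and lateral_pitch_um must be positive")

    @property
    def lateral_shape(self) -> Tuple[int, int]:
        return self.flow.shape[:2]

    @property
    def n_depth(self) -> int:
        return self.flow.shape[2]


@dataclass
class SurfaceMap:
    """Per-A-scan axial depths (µm) of the two choroidal reference surfaces.

    ``rpe_outer_depth_um`` anchors the slabs; ``csi_depth_um`` (the
    choroid–sclera interface) is needed for subfoveal choroidal thickness.
    """

    rpe_outer_depth_um: np.ndarray
    csi_depth_um: np.ndarray
    fovea_position: Tuple[int, int]

    def __post_init__(self) -> None:
        self.rpe_outer_depth_um = np.asarray(self.rpe_outer_depth_um, dtype=float)
        self.csi_depth_um = np.asarray(self.csi_depth_um, dtype=float)
        if self.rpe_outer_depth_um.shape != self.csi_depth_um.shape:
            raise ValueError("surface grids must share a shape")
        if self.rpe_outer_depth_um.ndim != 2:
            raise ValueError("surface maps must be 2-D lateral grids")
        if np.any(self.csi_depth_um < self.rpe_outer_depth_um):
            raise ValueError("choroid-sclera interface lies above the outer RPE somewhere")
        r, c = self.fovea_position
        nr, nc = self.rpe_outer_depth_um.shape
        if not (0 <= r < nr and 0 <= c < nc):
            raise ValueError(f"fovea_position {self.fovea_position} outside the {nr}x{nc} grid")

    @property
    def lateral_shape(self) -> Tuple[int, int]:
        return self.rpe_outer_depth_um.shape


@dataclass(frozen=True)
class SlabSpec:
    """An en-face slab: reference surface + axial offset + width.

    ``projection`` selects the depth-aggregation rule used when the slab
    is rendered into an en-face image.
    """

    offset_um: float
    width_um: float
    reference: Literal["rpe_outer"] = "rpe_outer"
    projection: Literal["max", "mean"] = "max"

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("width_um must be positive")
        if self.offset_um < 0:
            raise ValueError("offset_um must be non-negative")
        if self.reference != "rpe_outer":
            raise ValueError("only the outer RPE reference surface is supported")
        if self.projection not in ("max", "mean"):
            raise ValueError("projection must be 'max' or 'mean'")


#: Choriocapillaris slab used for the projection-artifact subtraction:
#: 30–60 µm below the outer RPE (widened from the device default so the
#: choriocapillaris signal is not missed).
CHORIOCAPILLARIS_SLAB = SlabSpec(offset_um=30.0, width_um=30.0)

#: The device's factory choriocapillaris preset (29–49 µm below the RPE).
DEVICE_DEFAULT_CC_SLAB = SlabSpec(offset_um=29.0, width_um=20.0)


@dataclass
class EnFaceImage:
    """A 2-D 8-bit en-face intensity image with slab provenance."""

    pixels: np.ndarray
    lateral_pitch_um: float | None = None
    slab_label: str = "other"

    def __post_init__(self) -> None:
        self.pixels = _as_uint8(self.pixels, "EnFaceImage.pixels")
        if self.pixels.ndim != 2:
            raise ValueError(f"en-face image must be 2-D, got shape {self.pixels.shape}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_label(self, label: str) -> "EnFaceImage":
        return replace(self, slab_label=label)


def measure_sct(surfaces: SurfaceMap, window_halfwidth: int = 0) -> float:
    """Subfoveal choroidal thickness (µm): the caliper distance from the
    outer RPE to the choroid–sclera interface at the fovea.

    ``window_halfwidth`` k > 0 replaces the single-A-scan reading by the
    median thickness over the (2k+1)² lateral window around the fovea
    (useful for noisy phantom surfaces; the default mimics a caliper).
    """
    r, c = surfaces.fovea_position
    thickness = surfaces.csi_depth_um - surfaces.rpe_outer_depth_um
    if window_halfwidth == 0:
        return float(thickness[r, c])
    k = int(window_halfwidth)
    nr, nc = thickness.shape
    window = thickness[max(r - k, 0) : r + k + 1, max(c - k, 0) : c + k + 1]
    return float(np.median(window))


def half_choroid_spec(
    sct_um: float,
    width_um: float = HALF_CHOROID_WIDTH_UM,
    placement: Literal["centered", "start"] = "centered",
    projection: Literal["max", "mean"] = "max",
) -> SlabSpec:
    """Slab specification for the half-choroid: a ``width_um`` window at
    one-half of the subfoveal choroidal thickness below the outer RPE.

    ``placement='centered'`` (default) centres the window on depth
    SCT/2; ``'start'`` begins it there instead.  Raises if the slab
    would reach the RPE, and warns when SCT is below the eligibility
    cutoff of {cut:.0f} µm.
    """
    if sct_um <= width_um:
        raise ValueError(
            f"SCT {sct_um} um is not larger than the slab width {width_um} um; "
            "the half-choroid slab would reach the RPE"
        )
    if sct_um < SCT_ELIGIBILITY_CUTOFF_UM:
        warnings.warn(
            f"SCT {sct_um:.0f} um is below the {SCT_ELIGIBILITY_CUTOFF_UM:.0f} um "
            "eligibility cutoff",
            ThinChoroidWarning,
            stacklevel=2,
        )
    if placement == "centered":
        offset = sct_um / 2.0 - width_um / 2.0
    elif placement == "start":
        offset = sct_um / 2.0
    else:
        raise ValueError("placement must be 'centered' or 'start'")
    if offset < 0:
        raise ValueError("half-choroid slab would start above the RPE")
    return SlabSpec(offset_um=offset, width_um=width_um, projection=projection)


half_choroid_spec.__doc__ = half_choroid_spec.__doc__.format(cut=SCT_ELIGIBILITY_CUTOFF_UM)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def resolve_slab(
    spec: SlabSpec, surfaces: SurfaceMap, volume: OCTAVolume
) -> Tuple[np.ndarray, np.ndarray]:
    """Convert a µm slab specification into per-A-scan axial index intervals.

    Returns ``(start, stop)`` integer arrays over the lateral grid such
    that depth samples ``start[r, c] <= i < stop[r, c]`` cover the µm
    interval [rpe + offset, rpe + offset + width).  Boundaries are
    rounded half-up in units of the axial pitch and the interval is
    forced non-empty (at least one sample).
    """
    if surfaces.lateral_shape != volume.lateral_shape:
        raise ValueError(
            f"surface grid {surfaces.lateral_shape} does not match volume lateral grid "
            f"{volume.lateral_shape}"
        )
    pitch = volume.axial_pitch_um
    top = surfaces.rpe_outer_depth_um + spec.offset_um
    start = _round_half_up(top / pitch)
    stop = _round_half_up((top + spec.width_um) / pitch)
    stop = np.maximum(stop, start + 1)
    bad = (start < 0) | (stop > volume.n_depth)
    if np.any(bad):
        rr, cc = np.nonzero(bad)
        head = ", ".join(f"({r}, {c})" for r, c in list(zip(rr, cc))[:5])
        raise ValueError(
            f"slab exits the volume axial extent at {bad.sum()} lateral position(s), "
            f"e.g. {head}"
        )
    return start, stop


def project_slab(
    volume: OCTAVolume,
    intervals: Tuple[np.ndarray, np.ndarray],
    projection: Literal["max", "mean"] = "max",
    slab_label: str = "other",
) -> EnFaceImage:
    """Aggregate the flow signal over per-A-scan depth intervals.

    ``max`` takes the brightest sample in the interval (the usual
    angiography slab rendering); ``mean`` averages and rounds half-up to
    8 bits.
    """
    start, stop = intervals
    if start.shape != volume.lateral_shape or stop.shape != volume.lateral_shape:
        raise ValueError("interval grids do not match the volume lateral grid")
    depth_idx = np.arange(volume.n_depth)
    inside = (depth_idx[None, None, :] >= start[:, :, None]) & (
        depth_idx[None, None, :] < stop[:, :, None]
    )
    flow = volume.flow.astype(np.int64)
    if projection == "max":
        out = np.where(inside, flow, -1).max(axis=2)
    elif projection == "mean":
        counts = inside.sum(axis=2)
        out = _round_half_up(np.where(inside, flow, 0).sum(axis=2) / counts)
    else:
        raise ValueError("projection must be 'max' or 'mean'")
    return EnFaceImage(
        pixels=out.astype(np.uint8),
        lateral_pitch_um=volume.lateral_pitch_um,
        slab_label=slab_label,
    )


def extract_slab(
    volume: OCTAVolume,
    surfaces: SurfaceMap,
    spec: SlabSpec,
    slab_label: str = "other",
) -> EnFaceImage:
    """Resolve and project a slab in one step."""
    return project_slab(volume, resolve_slab(spec, surfaces, volume), spec.projection, slab_label)
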