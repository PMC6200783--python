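"""Flow-area quantification: Bernsen local thresholding, optic-disc
exclusion, and the choroidal flow-area ratio.

The artifact-subtracted half-choroid image is binarized with Bernsen's
auto local threshold (per-pixel midpoint of the local min/max inside a
circular neighborhood, with a low-contrast fallback), the optic-disc
region is excluded with an oval mask on wide-field scans, and the flow
area is reported as the percentage of flow pixels among analyzed pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from .slab import EnFaceImage
from .subtraction import remove_projection_artifact, to_grayscale8, SubtractionChainResult

__all__ = [
    "BernsenParams",
    "OvalMask",
    "FlowRatioResult",
    "VesselsNotVisibleWarning",
    "bernsen_binarize",
    "make_oval_mask",
    "flow_area_ratio",
    "quantify_eye",
    "dice_coefficient",
]

#: Mean final-image intensity (8-bit) below which the choroidal vessels
#: are reported as not visible (the SD-OCTA regime).  A configuration
#: default, not a device constant.
DEFAULT_VISIBILITY_THRESHOLD = 5.0


class VesselsNotVisibleWarning(UserWarning):
    """Emitted when the artifact-subtracted image carries essentially no
    signal, so no choroidal vessel pattern can be quantified."""


@dataclass(frozen=True)
class BernsenParams:
    """Bernsen auto-local-threshold parameters.

    ``radius_px`` is the circular neighborhood radius; pixels whose
    local max−min contrast falls below ``contrast_threshold`` are
    classified by the midpoint against 128 instead of by their own
    intensity.  Defaults follow the ImageJ Auto Local Threshold plugin.
    """

    radius_px: int = 15
    contrast_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not (0 <= self.contrast_threshold <= 255):
            raise ValueError("contrast_threshold must lie in [0, 255]")


@dataclass
class OvalMask:
    """An elliptical exclusion region (the manual optic-disc selection).

    Pixel (r, c) is excluded iff ((r−r0)/a)² + ((c−c0)/b)² ≤ 1 with
    semi-axes (a, b) in pixels along (row, col).
    """

    center: Tuple[float, float]
    semi_axes: Tuple[float, float]
    shape: Tuple[int, int]
    inside_excluded: bool = True

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi_axes must be positive")
        r0, c0 = self.center
        nr, nc = self.shape
        if not (0 <= r0 < nr and 0 <= c0 < nc):
            raise ValueError(f"center {self.center} outside the {nr}x{nc} image")

    @property
    def excluded(self) -> np.ndarray:
        """Boolean grid of excluded pixels."""
        r0, c0 = self.center
        a, b = self.semi_axes
        rr = (np.arange(self.shape[0], dtype=float) - r0) / a
        cc = (np.arange(self.shape[1], dtype=float) - c0) / b
        inside = rr[:, None] ** 2 + cc[None, :] ** 2 <= 1.0
        return inside if self.inside_excluded else ~inside

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())


def make_oval_mask(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    semi_axes: Tuple[float, float],
) -> OvalMask:
    """Build the oval exclusion mask for an image of the given shape."""
    return OvalMask(center=center, semi_axes=semi_axes, shape=tuple(shape))


@dataclass
class FlowRatioResult:
    """Flow-area quantification of one eye."""

    ratio_pct: float
    n_flow_px: int
    n_analyzed_px: int
    params: BernsenParams
    exclusion: OvalMask | None = None
    vessels_visible: bool = True
    mean_final_intensity: float | None = None
    flow_mask: np.ndarray | None = field(default=None, repr=False)
    chain: SubtractionChainResult | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.n_flow_px <= self.n_analyzed_px):
            raise ValueError("flow pixel count exceeds analyzed pixel count")


def _disk_footprint(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return ax[:, None] ** 2 + ax[None, :] ** 2 <= radius**2


def bernsen_binarize(image: EnFaceImage | np.ndarray, params: BernsenParams | None = None) -> np.ndarray:
    """Bernsen auto local threshold.

    For each pixel, over the circular neighborhood of ``radius_px``
    intersected with the image at the borders (no padding): let
    ``mid = (local_max + local_min) / 2``.  If the local contrast
    ``local_max − local_min`` is below ``contrast_threshold`` the pixel
    is flow iff ``mid >= 128``; otherwise it is flow iff its own
    intensity is ``>= mid``.  Returns a boolean flow mask.
    """
    params = params or BernsenParams()
    px = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image, dtype=np.uint8)
    if px.ndim != 2:
        raise ValueError("bernsen_binarize expects a 2-D 8-bit image")
    if params.radius_px >= min(px.shape):
        raise ValueError(
            f"radius {params.radius_px} px is not smaller than the image extent {min(px.shape)} px"
        )
    foot = _disk_footprint(params.radius_px)
    # constant-mode extremes with neutral fill values realize the
    # "intersect the neighborhood with the image" border rule
    local_max = ndimage.maximum_filter(px, footprint=foot, mode="constant", cval=0)
    local_min = ndimage.minimum_filter(px, footprint=foot, mode="constant", cval=255)
    local_max = local_max.astype(np.float64)
    local_min = local_min.astype(np.float64)
    mid = (local_max + local_min) / 2.0
    low_contrast = (local_max - local_min) < params.contrast_threshold
    return np.where(low_contrast, mid >= 128.0, px >= mid)


def flow_area_ratio(
    flow_mask: np.ndarray,
    exclusion: OvalMask | None = None,
    params: BernsenParams | None = None,
) -> FlowRatioResult:
    """Percentage of flow pixels among all pixels outside the exclusion."""
    mask = np.asarray(flow_mask, dtype=bool)
    if exclusion is not None:
        if exclusion.shape != mask.shape:
            raise ValueError(
                f"exclusion shape {exclusion.shape} does not match mask shape {mask.shape}"
            )
        analyzed = ~exclusion.excluded
    else:
        analyzed = np.ones_like(mask)
    n_analyzed = int(analyzed.sum())
    if n_analyzed == 0:
        raise ValueError("exclusion covers the entire image; no pixels left to analyze")
    n_flow = int((mask & analyzed).sum())
    return FlowRatioResult(
        ratio_pct=100.0 * n_flow / n_analyzed,
        n_flow_px=n_flow,
        n_analyzed_px=n_analyzed,
        params=params or BernsenParams(),
        exclusion=exclusion,
        flow_mask=mask,
    )


def quantify_eye(
    cc: EnFaceImage | np.ndarray,
    hc: EnFaceImage | np.ndarray,
    bernsen: BernsenParams | None = None,
    disc: OvalMask | None = None,
    visibility_threshold: float = DEFAULT_VISIBILITY_THRESHOLD,
    keep_intermediates: bool = False,
) -> FlowRatioResult:
    """Full per-eye pipeline: grayscale → subtraction chain → Bernsen
    binarization → flow-area ratio.

    ``disc`` excludes the optic-disc region (wide-field scans only; the
    small-field SD-OCTA path passes ``None``).  When the mean intensity
    of the artifact-subtracted image falls below ``visibility_threshold``
    a :class:`VesselsNotVisibleWarning` is emitted and the result is
    flagged ``vessels_visible=False``.
    """
    bernsen = bernsen or BernsenParams()
    cc_img = to_grayscale8(cc) if not isinstance(cc, EnFaceImage) else cc
    hc_img = to_grayscale8(hc) if not isinstance(hc, EnFaceImage) else hc
    chain = remove_projection_artifact(cc_img, hc_img)
    mean_final = float(chain.final.pixels.mean())
    visible = mean_final >= visibility_threshold
    if not visible:
        warnings.warn(
            f"choroidal vessels not visible: mean subtracted-image intensity "
            f"{mean_final:.2f} < {visibility_threshold:g} (no flow signal reaches "
            "the half-choroid slab)",
            VesselsNotVisibleWarning,
            stacklevel=2,
        )
    flow_mask = bernsen_binarize(chain.final, bernsen)
    result = flow_area_ratio(flow_mask, disc, bernsen)
    result.vessels_visible = visible
    result.mean_final_intensity = mean_final
    if keep_intermediates:
        result.chain = chain
    return result


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks (1.0 if
    both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
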