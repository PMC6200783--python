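"""Choriocapillaris projection-artifact removal by iterated saturating subtraction.

In en-face OCTA slabs of the mid-choroid, flow in the overlying
choriocapillaris projects onto the choroidal stroma, so stroma appears
uniformly bright while the lumina of the middle/large choroidal vessels
appear dark.  The weak true flow signal inside the lumina can be
unveiled by a chain of three 8-bit saturating subtractions between the
choriocapillaris slab image (cc) and the half-choroid slab image (hc):

    sub_a = cc ⊖ hc      (the projection pattern, vessels bright)
    sub_b = hc ⊖ sub_a   (stroma retained, lumina near zero)
    final = hc ⊖ sub_b   (luminal flow retained, stroma removed)

where ``a ⊖ b = max(a − b, 0)`` pixelwise.  Algebraically the chain
collapses to ``final = min(max(cc − hc, 0), hc)``: stroma whose
brightness does not exceed the choriocapillaris is removed exactly, and
lumina whose stromal surround is at least twice as bright are recovered
exactly.  The saturating (clamped-at-zero) semantics of 8-bit image
subtraction are essential — without clamping the chain would collapse
to ``cc − hc``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .slab import EnFaceImage

__all__ = [
    "SubtractionChainResult",
    "to_grayscale8",
    "subtract_saturating",
    "remove_projection_artifact",
]

_REC601 = np.array([0.299, 0.587, 0.114])


@dataclass
class SubtractionChainResult:
    """The three images produced by the subtraction chain."""

    sub_a: EnFaceImage
    sub_b: EnFaceImage
    final: EnFaceImage
    inputs_label: str = ""


def to_grayscale8(
    image: EnFaceImage | np.ndarray,
    weights: Literal["mean", "rec601"] = "mean",
) -> EnFaceImage:
    """Convert an RGB or grayscale 8-bit image to single-channel 8-bit.

    RGB channels are collapsed by their unweighted mean, rounded half-up
    (``weights='rec601'`` uses Rec. 601 luma instead).  Grayscale input
    passes through unchanged.
    """
    if isinstance(image, EnFaceImage):
        return image
    arr = np.asarray(image)
    if arr.ndim == 2:
        return EnFaceImage(pixels=arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("RGB channels must lie in [0, 255]")
        chans = arr.astype(float)
        gray = chans @ _REC601 if weights == "rec601" else chans.mean(axis=2)
        return EnFaceImage(pixels=np.floor(gray + 0.5).astype(np.uint8))
    raise ValueError(
        f"unsupported channel count: expected 2-D grayscale or 3-channel RGB, got shape {arr.shape}"
    )


def _pixels(img: EnFaceImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, EnFaceImage) else np.asarray(img, dtype=np.uint8)


def subtract_saturating(a: EnFaceImage, b: EnFaceImage) -> EnFaceImage:
    """Pixelwise ``max(a − b, 0)`` on 8-bit images (no wraparound).

    This is the semantics of ImageJ's Image Calculator "Subtract" on
    8-bit images, the primitive all three chain steps use.
    """
    pa, pb = _pixels(a), _pixels(b)
    if pa.shape != pb.shape:
        raise ValueError(f"image dimensions differ: {pa.shape} vs {pb.shape}")
    out = np.where(pa >= pb, pa - pb, 0).astype(np.uint8)
    pitch = a.lateral_pitch_um if isinstance(a, EnFaceImage) else None
    return EnFaceImage(pixels=out, lateral_pitch_um=pitch)


def remove_projection_artifact(
    cc: EnFaceImage, hc: EnFaceImage, inputs_label: str = ""
) -> SubtractionChainResult:
    """Run the three-step subtraction chain on a choriocapillaris /
    half-choroid slab pair.

    Returns sub-A (cc ⊖ hc), sub-B (hc ⊖ sub-A) and the final
    artifact-free choroidal flow image (hc ⊖ sub-B).
    """
    sub_a = subtract_saturating(cc, hc).with_label("sub_a")
    sub_b = subtract_saturating(hc, sub_a).with_label("sub_b")
    final = subtract_saturating(hc, sub_b).with_label("final")
    return SubtractionChainResult(sub_a=sub_a, sub_b=sub_b, final=final, inputs_label=inputs_label)
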