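"""Synthetic OCTA phantoms with known ground truth.

The generator emulates the features of the choroidal slab pair that the
subtraction pipeline relies on: a laterally uniform, bright
choriocapillaris; dark middle/large-vessel lumina embedded in stroma at
half-choroid depth; a stromal "projection" signal proportional to the
overlying choriocapillaris signal (the artifact the pipeline removes);
additive Gaussian noise; and an SD-OCTA-like attenuation mode in which
essentially no flow signal reaches the half-choroid slab.

Vessel geometry is drawn as seeded random-walk tubes — adequate to
exercise binarization and area-ratio logic, with no claim to anatomical
(Sattler/Haller) realism.  All randomness flows from one master seed;
per-eye streams are derived deterministically from (seed, eye index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence, Tuple

import numpy as np

from .slab import EnFaceImage, OCTAVolume, SurfaceMap

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "PhantomEye",
    "generate_vessel_network",
    "render_phantom",
    "render_phantom_volume",
    "generate_phantom_eye",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomParams:
    """Phantom study conditions.

    ``artifact_gain`` scales the choriocapillaris intensity into the
    stromal projection signal (1.0 = stroma as bright as the
    choriocapillaris, the regime the subtraction method assumes);
    ``attenuation_mode='sd_octa'`` multiplies the entire half-choroid
    slab signal by ``sd_attenuation`` to emulate a spectral-domain
    device whose light does not reach the deep choroid.
    """

    grid: Tuple[int, int] = (192, 192)
    axial_pitch_um: float = 10.0
    sct_um: float = 300.0
    cc_intensity: int = 200
    lumen_intensity: int = 80
    artifact_gain: float = 1.0
    vessel_fraction: float = 0.25
    vessel_width_px: Tuple[int, int] = (3, 9)
    noise_sd: float = 8.0
    attenuation_mode: Literal["none", "sd_octa"] = "none"
    sd_attenuation: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.cc_intensity <= 255 and 0 <= self.lumen_intensity <= 255):
            raise ValueError("intensities must lie in [0, 255]")
        if not (0.0 <= self.artifact_gain <= 1.0):
            raise ValueError("artifact_gain must lie in [0, 1]")
        if self.lumen_intensity >= self.artifact_gain * self.cc_intensity:
            raise ValueError(
                "lumen_intensity must be below artifact_gain * cc_intensity for the "
                "dark-vessels-on-white-stroma appearance"
            )
        if not (0.0 < self.vessel_fraction < 1.0):
            raise ValueError("vessel_fraction must lie in (0, 1)")
        if not (0.0 < self.sd_attenuation <= 0.05):
            raise ValueError("sd_attenuation must lie in (0, 0.05]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom eye."""

    lumen_mask: np.ndarray
    params: PhantomParams
    sct_um: float


@dataclass
class PhantomEye:
    """One generated eye: the slab pair plus its ground truth."""

    cc: EnFaceImage
    hc: EnFaceImage
    truth: PhantomTruth
    sct_um: float


def _disk_offsets(radius: float) -> Tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1)
    dr, dc = np.meshgrid(ax, ax, indexing="ij")
    keep = dr**2 + dc**2 <= radius**2
    return dr[keep], dc[keep]


def generate_vessel_network(
    params: PhantomParams, seed: int | None = None
) -> np.ndarray:
    """Seeded random-walk vessel tubes covering approximately
    ``vessel_fraction`` of the lateral grid.

    Each stroke is a persistent random walk stamped with a disk whose
    diameter is drawn from ``vessel_width_px``; strokes are added until
    the target coverage is reached.  Deterministic for a fixed seed.
    """
    rows, cols = params.grid
    if rows < 64 or cols < 64:
        raise ValueError("grid must be at least 64 x 64")
    if params.vessel_fraction > 0.9:
        raise ValueError("vessel_fraction above 0.9 is unattainable for tube networks")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mask = np.zeros((rows, cols), dtype=bool)
    target_px = params.vessel_fraction * mask.size
    w_lo, w_hi = params.vessel_width_px
    max_steps = int(1.5 * max(rows, cols))
    for _ in range(1000):  # stroke budget; coverage normally converges in < 20
        if mask.sum() >= target_px:
            break
        width = rng.integers(w_lo, w_hi + 1)
        dr, dc = _disk_offsets(width / 2.0)
        # scale the stroke length to the remaining deficit to limit overshoot
        deficit = target_px - mask.sum()
        n_steps = int(np.clip(deficit / max(width, 1), 10, max_steps))
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        angle = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            rr = np.clip(int(round(r)) + dr, 0, rows - 1)
            cc = np.clip(int(round(c)) + dc, 0, cols - 1)
            mask[rr, cc] = True
            angle += rng.normal(0.0, 0.25)
            r = float(np.clip(r + np.sin(angle), 0, rows - 1))
            c = float(np.clip(c + np.cos(angle), 0, cols - 1))
    return mask


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def render_phantom(
    params: PhantomParams,
    lumen_mask: np.ndarray,
    rng: np.random.Generator | None = None,
) -> Tuple[EnFaceImage, EnFaceImage, PhantomTruth]:
    """Render the choriocapillaris / half-choroid slab pair.

    The choriocapillaris image is laterally uniform at ``cc_intensity``;
    the half-choroid image carries ``artifact_gain * cc_intensity`` on
    stroma (the projection artifact) and ``lumen_intensity`` on vessel
    lumina.  Gaussian noise of ``noise_sd`` is added to both slabs
    before 8-bit clipping.  In ``sd_octa`` mode the entire half-choroid
    slab (signal and noise alike) is scaled by ``sd_attenuation``.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if lumen_mask.shape != tuple(params.grid):
        raise ValueError("lumen_mask shape does not match the phantom grid")
    rng = rng or np.random.default_rng(params.seed)
    shape = lumen_mask.shape
    if params.noise_sd > 0:
        noise_cc = rng.normal(0.0, params.noise_sd, shape)
        noise_hc = rng.normal(0.0, params.noise_sd, shape)
    else:
        noise_cc = np.zeros(shape)
        noise_hc = np.zeros(shape)
    cc = _to_uint8(params.cc_intensity + noise_cc)
    hc_signal = np.where(
        lumen_mask, float(params.lumen_intensity), params.artifact_gain * params.cc_intensity
    )
    atten = params.sd_attenuation if params.attenuation_mode == "sd_octa" else 1.0
    hc = _to_uint8(atten * (hc_signal + noise_hc))
    truth = PhantomTruth(lumen_mask=lumen_mask, params=params, sct_um=params.sct_um)
    return (
        EnFaceImage(pixels=cc, slab_label="choriocapillaris"),
        EnFaceImage(pixels=hc, slab_label="half_choroid"),
        truth,
    )


def render_phantom_volume(
    params: PhantomParams,
    lumen_mask: np.ndarray,
    rng: np.random.Generator | None = None,
    rpe_depth_um: float = 50.0,
) -> Tuple[OCTAVolume, SurfaceMap]:
    """Render a full phantom flow volume with flat reference surfaces.

    Depth structure below the outer RPE: a bright choriocapillaris layer
    at 30–60 µm; deeper choroid (60 µm to the choroid–sclera interface
    at ``sct_um``) filled with the stromal projection signal except on
    the vessel columns of ``lumen_mask``, which carry the luminal flow
    signal.  Useful for exercising slab resolution and projection.
    """
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    rows, cols = lumen_mask.shape
    rng = rng or np.random.default_rng(params.seed)
    pitch = params.axial_pitch_um
    n_depth = int(np.ceil((rpe_depth_um + params.sct_um + 40.0) / pitch))
    depth_um = (np.arange(n_depth) + 0.5) * pitch  # sample centres
    vol = np.zeros((rows, cols, n_depth), dtype=float)
    cc_band = (depth_um >= rpe_depth_um + 30.0) & (depth_um < rpe_depth_um + 60.0)
    choroid_band = (depth_um >= rpe_depth_um + 60.0) & (depth_um < rpe_depth_um + params.sct_um)
    vol[:, :, cc_band] = params.cc_intensity
    stroma = params.artifact_gain * params.cc_intensity
    choroid = np.where(lumen_mask, float(params.lumen_intensity), stroma)
    vol[:, :, choroid_band] = choroid[:, :, None]
    if params.attenuation_mode == "sd_octa":
        vol[:, :, choroid_band] *= params.sd_attenuation
    if params.noise_sd > 0:
        vol += rng.normal(0.0, params.noise_sd, vol.shape)
    volume = OCTAVolume(
        flow=_to_uint8(vol),
        axial_pitch_um=pitch,
        lateral_pitch_um=12000.0 / cols,  # nominal 12 mm wide-field scan
        field_size_mm=(12.0, 12.0),
    )
    surfaces = SurfaceMap(
        rpe_outer_depth_um=np.full((rows, cols), rpe_depth_um),
        csi_depth_um=np.full((rows, cols), rpe_depth_um + params.sct_um),
        fovea_position=(rows // 2, cols // 2),
    )
    return volume, surfaces


def generate_phantom_eye(params: PhantomParams, seed: int | None = None) -> PhantomEye:
    """Vessel network + slab rendering with one derived random stream."""
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_net, s_render = ss.spawn(2)
    mask = generate_vessel_network(params, seed=s_net)
    cc, hc, truth = render_phantom(params, mask, rng=np.random.default_rng(s_render))
    return PhantomEye(cc=cc, hc=hc, truth=truth, sct_um=params.sct_um)


def generate_cohort(
    n_eyes: int,
    seed: int,
    coupling: float = 0.5,
    base_params: PhantomParams | None = None,
    sct_range_um: Tuple[float, float] = (180.0, 500.0),
    fraction_range: Tuple[float, float] = (0.12, 0.40),
) -> list[PhantomEye]:
    """Generate a cohort of phantom eyes with a controllable SCT–vessel
    association.

    Per eye, SCT is drawn uniformly from ``sct_range_um`` and the
    vessel-area fraction is a ``coupling``-weighted mix of the (scaled)
    SCT and an independent uniform draw, mapped into ``fraction_range``:
    ``coupling=1`` makes vessel area a deterministic function of SCT,
    ``coupling=0`` makes them independent.  Per-eye streams derive
    deterministically from ``(seed, eye index)``.
    """
    if n_eyes < 5:
        raise ValueError("need at least 5 eyes for a cohort")
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    base = base_params or PhantomParams()
    lo, hi = sct_range_um
    f_lo, f_hi = fraction_range
    eyes: list[PhantomEye] = []
    for i in range(n_eyes):
        ss = np.random.SeedSequence(entropy=(int(seed), int(i)))
        rng = np.random.default_rng(ss)
        sct = rng.uniform(lo, hi)
        t = (sct - lo) / (hi - lo)
        u = rng.uniform()
        fraction = f_lo + (f_hi - f_lo) * (coupling * t + (1.0 - coupling) * u)
        params = replace(base, sct_um=float(sct), vessel_fraction=float(fraction))
        s_net, s_render = ss.spawn(2)
        mask = generate_vessel_network(params, seed=s_net)
        cc, hc, truth = render_phantom(params, mask, rng=np.random.default_rng(s_render))
        eyes.append(PhantomEye(cc=cc, hc=hc, truth=truth, sct_um=float(sct)))
    return eyes
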