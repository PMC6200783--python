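"""Image, volume and table I/O.

En-face images travel as single-page 8-bit grayscale TIFF or PNG
(8-bit RGB accepted on read and collapsed to grayscale).  Volumes are
multi-page grayscale TIFFs — one en-face depth plane per page — with a
JSON sidecar carrying the pitches, reference-surface depths and fovea
position.  Cohort tables are UTF-8 CSV with a required header.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cohort import COHORT_COLUMNS, CohortSummary, EyeRecord, frame_to_records
from .slab import EnFaceImage, OCTAVolume, SurfaceMap
from .subtraction import to_grayscale8

__all__ = [
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_summary",
]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def read_image(path: str | Path, slab_label: str = "other") -> EnFaceImage:
    """Read an 8-bit grayscale or RGB TIFF/PNG as an :class:`EnFaceImage`.

    RGB is collapsed by unweighted channel mean; 16-bit input is
    rejected (rescale to 8-bit before import rather than silently
    truncating flow intensities).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r}; use TIFF or PNG")
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"{path}: zero-size image")
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: {arr.dtype} images are not supported; convert to 8-bit "
            "(scale intensities into [0, 255]) before import"
        )
    return to_grayscale8(arr).with_label(slab_label)


def write_image(path: str | Path, image: EnFaceImage | np.ndarray) -> Path:
    """Write an 8-bit grayscale image; format chosen by extension."""
    path = Path(path)
    px = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px, photometric="minisblack")
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, px)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}; use TIFF or PNG")
    return path


def write_volume(
    path: str | Path, volume: OCTAVolume, surfaces: SurfaceMap | None = None
) -> Path:
    """Write a volume as a multi-page TIFF (one depth plane per page)
    plus a ``.json`` sidecar with geometry and surfaces."""
    path = Path(path)
    planes = np.moveaxis(volume.flow, 2, 0)  # pages along depth
    tifffile.imwrite(path, planes, photometric="minisblack")
    header: dict = {
        "axial_pitch_um": volume.axial_pitch_um,
        "lateral_pitch_um": volume.lateral_pitch_um,
        "field_size_mm": list(volume.field_size_mm) if volume.field_size_mm else None,
    }
    if surfaces is not None:
        header["rpe_outer_depth_um"] = surfaces.rpe_outer_depth_um.tolist()
        header["csi_depth_um"] = surfaces.csi_depth_um.tolist()
        header["fovea_position"] = list(surfaces.fovea_position)
    path.with_suffix(".json").write_text(json.dumps(header))
    return path


def read_volume(path: str | Path) -> tuple[OCTAVolume, SurfaceMap | None]:
    """Read a multi-page TIFF volume and its JSON sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"volume sidecar {sidecar} not found")
    header = json.loads(sidecar.read_text())
    planes = tifffile.imread(path)
    if planes.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page volume, got shape {planes.shape}")
    volume = OCTAVolume(
        flow=np.moveaxis(planes, 0, 2),
        axial_pitch_um=float(header["axial_pitch_um"]),
        lateral_pitch_um=float(header["lateral_pitch_um"]),
        field_size_mm=tuple(header["field_size_mm"]) if header.get("field_size_mm") else None,
    )
    surfaces = None
    if "rpe_outer_depth_um" in header:
        surfaces = SurfaceMap(
            rpe_outer_depth_um=np.asarray(header["rpe_outer_depth_um"], dtype=float),
            csi_depth_um=np.asarray(header["csi_depth_um"], dtype=float),
            fovea_position=tuple(header["fovea_position"]),
        )
    return volume, surfaces


def read_cohort_csv(path: str | Path) -> list[EyeRecord]:
    """Read a cohort table, validating rows and reporting offenders by
    line number.  Duplicate (case_id, laterality) pairs are rejected."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty cohort file") from None
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: list[EyeRecord] = []
    errors: list[str] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            records.append(
                EyeRecord(
                    case_id=int(row.case_id),
                    eye_index=int(row.eye_index),
                    laterality=str(row.laterality).strip(),
                    sex=str(row.sex).strip(),
                    age=float(row.age),
                    sct_um=float(row.sct_um),
                    flow_pct=float(row.flow_pct),
                    sd_octa_examined=str(row.sd_octa).strip() == "+",
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    seen: dict[tuple, int] = {}
    for pos, r in enumerate(records):
        key = (r.case_id, r.laterality)
        if key in seen:
            raise ValueError(
                f"{path}: duplicate (case_id, laterality) {key} at lines "
                f"{seen[key] + 2} and {pos + 2}"
            )
        seen[key] = pos
    return records


def write_cohort_csv(path: str | Path, records: list[EyeRecord]) -> Path:
    from .cohort import records_to_frame

    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_summary(summary: CohortSummary | dict, path: str | Path) -> Path:
    """Emit a summary (or any report dict) as JSON."""
    path = Path(path)
    payload = _jsonable(summary)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
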