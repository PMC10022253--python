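"""File I/O: volumes (NIfTI/NRRD), fiducials (Slicer markups / CSV), cohorts.

All readers convert geometry to the LPS patient-space convention.  Slicer
markup files natively store RAS unless the file declares otherwise, so
fiducial coordinates are sign-flipped on load; NIfTI affines (RAS-coded) are
converted by SimpleITK on read.  Plain-CSV fiducials are taken as already LPS.

DICOM series are intentionally not read here; convert to NIfTI or NRRD first.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, LandmarkError
from .geometry import ScapularLandmarks, lps_to_ras, ras_to_lps
from .image import SegmentationMask, VolumeImage

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "read_fiducials", "write_fiducials", "read_cohort", "write_cohort",
           "DEFAULT_LANDMARK_ALIASES"]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".nrrd")

#: case-insensitive aliases (punctuation/whitespace stripped) per landmark
DEFAULT_LANDMARK_ALIASES: dict[str, tuple[str, ...]] = {
    "angulus_inferior": ("ai", "angulusinferior", "angularinferior", "inferiorangle"),
    "trigonum_scapulae": ("ts", "trigonumscapulae", "trigonum"),
    "glenoid_center": ("gc", "glenoidcenter", "glenoidcentre", "glenoid"),
}


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"{path}: unsupported volume format "
                          f"(expected one of {_VOLUME_SUFFIXES})")


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI or NRRD volume, converting geometry to LPS.

    SimpleITK expresses origins and direction cosines in LPS regardless of the
    on-disk convention, so NIfTI RAS affines arrive with x and y negated.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises bare RuntimeError on corrupt files
        raise FormatError(f"{path}: could not be read as NIfTI/NRRD ({exc})") from exc
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (k,j,i) -> (i,j,k)
    return VolumeImage(voxels=voxels,
                       spacing=np.array(img.GetSpacing()),
                       origin=np.array(img.GetOrigin()),
                       direction=np.array(img.GetDirection()).reshape(3, 3))


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI or NRRD (format chosen by extension)."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.direction.ravel()))
    sitk.WriteImage(img, str(path))
    return path


def read_mask(path: str | Path) -> SegmentationMask:
    """Read a binary segmentation mask (values 0/1) from NIfTI/NRRD."""
    v = read_volume(path)
    return SegmentationMask(voxels=v.voxels, spacing=v.spacing,
                            origin=v.origin, direction=v.direction)


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    return write_volume(mask, path)


def _resolve_label(label: str, aliases: dict[str, tuple[str, ...]]) -> str | None:
    key = "".join(ch for ch in label.lower() if ch.isalnum())
    for canonical, names in aliases.items():
        if key == "".join(ch for ch in canonical if ch.isalnum()) or key in names:
            return canonical
    return None


def _parse_mrk_json(path: Path) -> tuple[list[tuple[str, np.ndarray]], str]:
    try:
        data = json.loads(path.read_text())
        markups = data["markups"][0]
        points = [(cp["label"], np.asarray(cp["position"], dtype=float))
                  for cp in markups["controlPoints"]]
    except (json.JSONDecodeError, KeyError, IndexError, TypeError) as exc:
        raise FormatError(f"{path}: not a valid Slicer markups JSON file ({exc})") from exc
    return points, str(markups.get("coordinateSystem", "RAS")).upper()


def _parse_fcsv(path: Path) -> tuple[list[tuple[str, np.ndarray]], str]:
    system = "RAS"
    points = []
    try:
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                if "coordinatesystem" in line.replace(" ", "").lower():
                    val = line.split("=")[-1].strip()
                    system = {"0": "RAS", "1": "LPS"}.get(val, val.upper())
                continue
            fields = line.split(",")
            if len(fields) < 12:
                continue
            points.append((fields[11], np.array(fields[1:4], dtype=float)))
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: not a valid fcsv markups file ({exc})") from exc
    return points, system


def _parse_plain_csv(path: Path) -> tuple[list[tuple[str, np.ndarray]], str]:
    points = []
    try:
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in ("name", "label"):
                    continue
                points.append((row[0].strip(), np.array(row[1:4], dtype=float)))
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: not a valid name,x,y,z landmark CSV ({exc})") from exc
    return points, "LPS"  # plain CSV is taken as already LPS


def read_fiducials(path: str | Path, side: str = "right",
                   aliases: dict[str, tuple[str, ...]] | None = None) -> ScapularLandmarks:
    """Read the three scapular landmarks from .mrk.json, .fcsv, or plain CSV.

    Slicer files are converted from RAS to LPS (unless the file declares LPS);
    landmark names are matched case-insensitively against configurable aliases.

    Raises
    ------
    LandmarkError
        If any of the three landmarks is missing, listing what was found.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    aliases = {**DEFAULT_LANDMARK_ALIASES, **(aliases or {})}
    name = path.name.lower()
    if name.endswith(".mrk.json") or name.endswith(".json"):
        points, system = _parse_mrk_json(path)
    elif name.endswith(".fcsv"):
        points, system = _parse_fcsv(path)
    elif name.endswith(".csv"):
        points, system = _parse_plain_csv(path)
    else:
        raise FormatError(f"{path}: unsupported fiducial format "
                          "(expected .mrk.json, .fcsv, or .csv)")

    found: dict[str, np.ndarray] = {}
    for label, pos in points:
        canonical = _resolve_label(label, aliases)
        if canonical is not None:
            found[canonical] = ras_to_lps(pos) if system == "RAS" else pos
    missing = [k for k in DEFAULT_LANDMARK_ALIASES if k not in found]
    if missing:
        raise LandmarkError(
            f"{path}: missing landmark(s) {missing}; recognized labels found: "
            f"{sorted(found)} among file labels {[lab for lab, _ in points]}")
    return ScapularLandmarks(found["angulus_inferior"], found["trigonum_scapulae"],
                             found["glenoid_center"], side=side)


def write_fiducials(landmarks: ScapularLandmarks, path: str | Path) -> Path:
    """Write the landmarks as a Slicer markups .mrk.json file (stored RAS)."""
    path = Path(path)
    cps = []
    for i, (label, point) in enumerate([
            ("angulus_inferior", landmarks.angulus_inferior),
            ("trigonum_scapulae", landmarks.trigonum_scapulae),
            ("glenoid_center", landmarks.glenoid_center)]):
        cps.append({"id": str(i + 1), "label": label,
                    "position": lps_to_ras(point).tolist()})
    data = {"@schema": "https://raw.githubusercontent.com/slicer/slicer/master/"
                       "Modules/Loadable/Markups/Resources/Schema/"
                       "markups-schema-v1.0.3.json",
            "markups": [{"type": "Fiducial", "coordinateSystem": "RAS",
                         "coordinateUnits": "mm", "controlPoints": cps}]}
    path.write_text(json.dumps(data, indent=2) + "\n")
    return path


def read_cohort(path: str | Path):
    """Read a cohort CSV (per-patient volumes + ROM) into a DataFrame."""
    import pandas as pd
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    df = pd.read_csv(path)
    if "patient_id" in df.columns and df["patient_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate patient_id values")
    return df


def write_cohort(cohort, path: str | Path) -> Path:
    """Write a cohort DataFrame as CSV (deterministic column order preserved)."""
    path = Path(path)
    cohort.to_csv(path, index=False, lineterminator="\n")
    return path
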