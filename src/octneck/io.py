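"""Calibrated data model and on-disk formats.

An HF-OCT pullback is stored as a multi-page 16-bit TIFF stack (one page per
cross-sectional frame) plus a JSON sidecar with the acquisition geometry.
Manual wall/neck annotations are JSON; the per-aneurysm study table is CSV.

Conventions: frames and image rows/columns are 0-based with the origin at the
top-left pixel; angles are radians in [0, 2*pi), counter-clockwise from the +x
(column) axis with +y along increasing row index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import AnnotationError, CalibrationError, FormatError, ValidationError

__all__ = [
    "AcquisitionGeometry",
    "OCTVolume",
    "WallAnnotation",
    "CaseRecord",
    "read_volume",
    "write_volume",
    "read_annotation",
    "write_annotation",
    "read_case_table",
    "write_case_table",
    "load_reference_cases",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical calibration of a pullback.

    Parameters
    ----------
    radial_spacing_um
        Length per radial sample, micrometres.  On the order of the system's
        ~10 um axial resolution.
    n_alines
        Angular samples (A-lines) per frame.
    frame_pitch_um
        Pullback distance between consecutive frames, micrometres.
    catheter_center_xy
        (x, y) = (column, row) of the imaging-core axis in pixel coordinates,
        or ``None`` to use the geometric frame centre.
    """

    radial_spacing_um: float
    n_alines: int
    frame_pitch_um: float
    catheter_center_xy: tuple[float, float] | None = None

    def __post_init__(self):
        if not (self.radial_spacing_um > 0):
            raise CalibrationError(f"radial_spacing_um must be > 0, got {self.radial_spacing_um}")
        if not (self.frame_pitch_um > 0):
            raise CalibrationError(f"frame_pitch_um must be > 0, got {self.frame_pitch_um}")
        if int(self.n_alines) != self.n_alines or self.n_alines < 8:
            raise CalibrationError(f"n_alines must be an integer >= 8, got {self.n_alines}")

    @property
    def theta_step(self) -> float:
        """Angular step between adjacent A-lines, radians."""
        return TWO_PI / self.n_alines

    def to_dict(self) -> dict:
        return {
            "radial_spacing_um": self.radial_spacing_um,
            "frame_pitch_um": self.frame_pitch_um,
            "n_alines": int(self.n_alines),
            "catheter_center_xy": (
                list(self.catheter_center_xy) if self.catheter_center_xy is not None else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        try:
            center = d.get("catheter_center_xy")
            return cls(
                radial_spacing_um=float(d["radial_spacing_um"]),
                n_alines=int(d["n_alines"]),
                frame_pitch_um=float(d["frame_pitch_um"]),
                catheter_center_xy=tuple(center) if center is not None else None,
            )
        except KeyError as exc:
            raise CalibrationError(f"metadata missing required key: {exc}") from exc


@dataclass
class OCTVolume:
    """A calibrated 3D pullback: ``frames[z, row, col]`` of unsigned intensities."""

    frames: np.ndarray
    geometry: AcquisitionGeometry
    intensity_max: int = 65535

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValidationError(f"frames must be 3D with >= 1 frame, got shape {self.frames.shape}")
        if not np.issubdtype(self.frames.dtype, np.unsignedinteger):
            raise ValidationError(f"frames must have an unsigned integer dtype, got {self.frames.dtype}")
        if self.intensity_max <= 0 or self.intensity_max > 65535:
            raise ValidationError(f"intensity_max must be in (0, 65535], got {self.intensity_max}")
        if self.frames.size and int(self.frames.max()) > self.intensity_max:
            raise ValidationError(
                f"intensity {int(self.frames.max())} exceeds intensity_max {self.intensity_max}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def center_for_frame(self, z: int) -> tuple[float, float]:
        """Catheter centre (x, y) for frame ``z`` (defaults to the frame centre)."""
        if self.geometry.catheter_center_xy is not None:
            return self.geometry.catheter_center_xy
        rows, cols = self.frame_shape
        return ((cols - 1) / 2.0, (rows - 1) / 2.0)


def _norm_interval(iv) -> tuple[float, float]:
    t0, t1 = float(iv[0]) % TWO_PI, float(iv[1]) % TWO_PI
    return t0, t1


@dataclass
class WallAnnotation:
    """Manual vessel-wall tracing and neck (ostium) localisation.

    ``traces`` maps frame index -> sequence of (theta, radius_um) control
    points of the vessel wall, listed outside the ostium.  ``neck_frames`` is
    the inclusive frame range of the aneurysm neck and ``neck_angles`` the
    angular interval(s) of the ostium, each (start, end) in radians and
    allowed to wrap across 0 when start > end.
    """

    traces: dict[int, list[tuple[float, float]]]
    neck_frames: tuple[int, int]
    neck_angles: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        z0, z1 = self.neck_frames
        if z0 > z1 or z0 < 0:
            raise AnnotationError(f"invalid neck frame range {self.neck_frames}")
        self.neck_frames = (int(z0), int(z1))
        self.neck_angles = [_norm_interval(iv) for iv in self.neck_angles]
        for z, pts in self.traces.items():
            if len(pts) < 3:
                raise AnnotationError(f"frame {z}: wall trace needs >= 3 control points, got {len(pts)}")

    def to_dict(self) -> dict:
        return {
            "frames": {str(z): [[float(t), float(r)] for t, r in pts] for z, pts in self.traces.items()},
            "neck_frames": list(self.neck_frames),
            "neck_angles": [list(iv) for iv in self.neck_angles],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WallAnnotation":
        try:
            traces = {int(z): [(float(t), float(r)) for t, r in pts] for z, pts in d["frames"].items()}
            return cls(
                traces=traces,
                neck_frames=tuple(d["neck_frames"]),
                neck_angles=[tuple(iv) for iv in d.get("neck_angles", [])],
            )
        except KeyError as exc:
            raise FormatError(f"annotation JSON missing key: {exc}") from exc


_LOCATIONS = {"sidewall", "bifurcation"}
_DEVICES = {"NGID", "coils"}
_GRADES = {1, 2, 3}


@dataclass(frozen=True)
class CaseRecord:
    """One treated aneurysm: device, implant count, largest neck gap, DSA grades.

    ``largest_gap_mm2`` is ``None`` exactly for coil cases, where optical
    attenuation by the coil mass precludes the neck analysis.
    """

    animal_id: str
    location: str
    device: str
    n_implants: int
    herniation: bool
    largest_gap_mm2: float | None
    dsa_implant: int
    dsa_180d: int

    def __post_init__(self):
        if self.location not in _LOCATIONS:
            raise ValidationError(f"location must be one of {_LOCATIONS}, got {self.location!r}")
        if self.device not in _DEVICES:
            raise ValidationError(f"device must be one of {_DEVICES}, got {self.device!r}")
        if self.n_implants < 1:
            raise ValidationError(f"n_implants must be positive, got {self.n_implants}")
        if self.dsa_implant not in _GRADES or self.dsa_180d not in _GRADES:
            raise ValidationError(
                f"DSA grades must be in {_GRADES}, got {self.dsa_implant}/{self.dsa_180d}"
            )
        if self.device == "coils" and self.largest_gap_mm2 is not None:
            raise ValidationError("largest_gap_mm2 must be missing for coil cases")
        if self.device == "NGID":
            if self.largest_gap_mm2 is None:
                raise ValidationError("largest_gap_mm2 is required for NGID cases")
            if self.largest_gap_mm2 < 0:
                raise ValidationError(f"largest_gap_mm2 must be >= 0, got {self.largest_gap_mm2}")


# ---------------------------------------------------------------------------
# volume I/O


def read_volume(path_stack, path_meta) -> OCTVolume:
    """Read a pullback from a multi-page TIFF stack + JSON geometry sidecar."""
    with open(path_meta) as fh:
        meta = json.load(fh)
    geometry = AcquisitionGeometry.from_dict(meta)
    intensity_max = int(meta.get("intensity_max", 65535))
    frames = tifffile.imread(path_stack)
    frames = np.asarray(frames)
    if frames.ndim == 2:  # single-page stack
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(f"expected a stack of 2D pages, got array of shape {frames.shape}")
    return OCTVolume(frames=frames, geometry=geometry, intensity_max=intensity_max)


def write_volume(volume: OCTVolume, path_stack, path_meta) -> None:
    """Write a pullback so that :func:`read_volume` round-trips it bit-exactly."""
    frames = volume.frames
    if frames.dtype != np.uint16:
        if int(frames.max(initial=0)) > 65535:
            raise ValidationError("intensities exceed 16-bit range")
        frames = frames.astype(np.uint16)
    tifffile.imwrite(path_stack, frames, photometric="minisblack")
    meta = volume.geometry.to_dict()
    meta["intensity_max"] = int(volume.intensity_max)
    with open(path_meta, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_annotation(path) -> WallAnnotation:
    with open(path) as fh:
        return WallAnnotation.from_dict(json.load(fh))


def write_annotation(annotation: WallAnnotation, path) -> None:
    with open(path, "w") as fh:
        json.dump(annotation.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# case table I/O

CASE_COLUMNS = [
    "animal_id",
    "location",
    "device",
    "n_implants",
    "herniation",
    "largest_gap_mm2",
    "dsa_implant",
    "dsa_180d",
]

_TRUTHY = {"y", "yes", "true", "1"}
_FALSY = {"n", "no", "false", "0"}


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot parse boolean field {v!r}")


def read_case_table(path) -> list[CaseRecord]:
    """Read the per-aneurysm study table (CSV, one row per treated aneurysm)."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    if df.empty:
        return []
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"case table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        gap = row["largest_gap_mm2"]
        gap = None if pd.isna(gap) else float(gap)
        records.append(
            CaseRecord(
                animal_id=str(row["animal_id"]),
                location=str(row["location"]),
                device=str(row["device"]),
                n_implants=int(row["n_implants"]),
                herniation=_parse_bool(row["herniation"]),
                largest_gap_mm2=gap,
                dsa_implant=int(row["dsa_implant"]),
                dsa_180d=int(row["dsa_180d"]),
            )
        )
    return records


def write_case_table(records: Sequence[CaseRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "location": r.location,
                "device": r.device,
                "n_implants": r.n_implants,
                "herniation": "Y" if r.herniation else "N",
                "largest_gap_mm2": "" if r.largest_gap_mm2 is None else r.largest_gap_mm2,
                "dsa_implant": r.dsa_implant,
                "dsa_180d": r.dsa_180d,
            }
        )
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)


def load_reference_cases() -> list[CaseRecord]:
    """The 11-aneurysm canine study table distributed with the package.

    Six dogs, one sidewall and one bifurcation aneurysm each; one untreated
    sidewall aneurysm is excluded.  Seven aneurysms received intrasaccular
    devices (NGID) and four were coiled.  This is the reference dataset for
    the statistics workflows.
    """
    with resources.as_file(resources.files("octneck.data") / "study_cases.csv") as p:
        return read_case_table(p)
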