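"""Coordinate transforms and neck-surface reconstruction.

Cross-sectional frames are remapped into polar coordinates about the catheter
centre so that every row is one A-line (a radial depth profile).  The manually
traced vessel wall and ostium interval are interpolated onto the same angular
grid, and the aneurysm-neck surface is reconstructed as a (frame x angle) grid
of cells with physical areas in mm^2.

The area element uses the local wall radius (cylindrical-patch approximation):
``cell_area = frame_pitch * cell_radius * theta_step``, with lengths in mm.
Arc length at the wall is the physically correct width of a coverage cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import AnnotationError, GeometryError
from .io import TWO_PI, AcquisitionGeometry, WallAnnotation

__all__ = [
    "PolarFrame",
    "NeckSurface",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "interpolate_wall",
    "build_neck_surface",
    "angle_in_interval",
]

_EPS = 1e-9


@dataclass
class PolarFrame:
    """One frame resampled on a polar grid: ``alines[theta_index, r_index]``.

    Row 0 is theta = 0 at the +x axis, increasing counter-clockwise; radial
    sample 0 sits at the catheter centre.
    """

    alines: np.ndarray
    theta_step: float
    radial_spacing_um: float

    @property
    def n_angles(self) -> int:
        return self.alines.shape[0]

    @property
    def n_radii(self) -> int:
        return self.alines.shape[1]


def cartesian_to_polar(
    frame: np.ndarray,
    center: tuple[float, float],
    n_angles: int,
    n_radii: int,
    radial_spacing_um: float,
    pixel_pitch_um: float | None = None,
) -> PolarFrame:
    """Resample a Cartesian frame onto a polar (A-line) grid.

    ``alines[t, r]`` is the bilinear interpolation of ``frame`` at
    ``center + r * radial_spacing * (cos theta, sin theta)``; samples falling
    outside the frame read as 0.  ``pixel_pitch_um`` is the physical size of a
    Cartesian pixel and defaults to ``radial_spacing_um`` (isotropic grid).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise GeometryError(f"frame must be 2D, got shape {frame.shape}")
    if n_angles < 8 or n_radii < 8:
        raise GeometryError("n_angles and n_radii must be >= 8")
    cx, cy = center
    rows, cols = frame.shape
    if not (0 <= cx <= cols - 1 and 0 <= cy <= rows - 1):
        raise GeometryError(f"catheter center {center} outside frame of shape {frame.shape}")
    if pixel_pitch_um is None:
        pixel_pitch_um = radial_spacing_um

    theta = np.arange(n_angles) * (TWO_PI / n_angles)
    r_px = np.arange(n_radii) * (radial_spacing_um / pixel_pitch_um)
    xs = cx + r_px[None, :] * np.cos(theta)[:, None]
    ys = cy + r_px[None, :] * np.sin(theta)[:, None]
    alines = ndimage.map_coordinates(frame, [ys.ravel(), xs.ravel()], order=1, cval=0.0)
    return PolarFrame(
        alines=alines.reshape(n_angles, n_radii),
        theta_step=TWO_PI / n_angles,
        radial_spacing_um=radial_spacing_um,
    )


def polar_to_cartesian(
    polar: PolarFrame,
    shape: tuple[int, int],
    center: tuple[float, float],
    pixel_pitch_um: float | None = None,
) -> np.ndarray:
    """Inverse remap of :func:`cartesian_to_polar` (bilinear, wrap in theta).

    Pixels beyond the sampled radial extent read as 0.
    """
    if pixel_pitch_um is None:
        pixel_pitch_um = polar.radial_spacing_um
    rows, cols = shape
    cx, cy = center
    yy, xx = np.mgrid[0:rows, 0:cols]
    dx = (xx - cx) * pixel_pitch_um
    dy = (yy - cy) * pixel_pitch_um
    r_idx = np.hypot(dx, dy) / polar.radial_spacing_um
    t_idx = (np.arctan2(dy, dx) % TWO_PI) / polar.theta_step
    # pad one wrapped row so interpolation across theta = 2*pi is seamless
    padded = np.vstack([polar.alines, polar.alines[:1]])
    out = ndimage.map_coordinates(padded, [t_idx.ravel(), r_idx.ravel()], order=1, cval=0.0)
    return out.reshape(shape)


def angle_in_interval(theta, interval: tuple[float, float]) -> np.ndarray:
    """Membership of angle(s) in a half-open interval [t0, t1) that may wrap 0.

    A zero-width interval is empty (a full circle cannot be expressed as one
    interval; it never arises for a saccular ostium).
    """
    t0, t1 = interval[0] % TWO_PI, interval[1] % TWO_PI
    th = np.asarray(theta) % TWO_PI
    if abs(t0 - t1) < _EPS:
        return np.zeros_like(th, dtype=bool)
    if t0 < t1:
        return (th >= t0 - _EPS) & (th < t1 - _EPS)
    # wrapping interval, e.g. [7*pi/4, pi/4)
    return (th >= t0 - _EPS) | (th < t1 - _EPS)


def interpolate_wall(
    annotation: WallAnnotation, frame_index: int, n_angles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle wall radius for one frame, with ostium cells flagged.

    Returns ``(radius_um, ostium_mask)``, both of length ``n_angles`` on the
    grid ``theta_k = k * 2*pi / n_angles``.  The radius is the periodic linear
    interpolation of the traced control points; over the ostium (where the
    wall is absent) the radius is bridged across the interval endpoints,
    because the device sits at the level of the missing wall.
    """
    if frame_index not in annotation.traces:
        raise AnnotationError(f"no wall trace for frame {frame_index}")
    pts = sorted((t % TWO_PI, r) for t, r in annotation.traces[frame_index])
    if len(pts) < 3:
        raise AnnotationError("wall trace needs >= 3 control points")
    th = np.array([p[0] for p in pts])
    rr = np.array([p[1] for p in pts])
    theta = np.arange(n_angles) * (TWO_PI / n_angles)
    # periodic linear interpolation: extend one point on each side
    th_ext = np.concatenate([[th[-1] - TWO_PI], th, [th[0] + TWO_PI]])
    rr_ext = np.concatenate([[rr[-1]], rr, [rr[0]]])
    radius = np.interp(theta, th_ext, rr_ext)

    z0, z1 = annotation.neck_frames
    mask = np.zeros(n_angles, dtype=bool)
    if z0 <= frame_index <= z1:
        for iv in annotation.neck_angles:
            mask |= angle_in_interval(theta, iv)
    return radius, mask


@dataclass
class NeckSurface:
    """The unrolled aneurysm-neck surface: one cell per (frame, angle step).

    ``angle_indices`` are A-line indices ordered contiguously around any wrap
    across theta = 0, so adjacent grid columns are physically adjacent.
    """

    frame_indices: np.ndarray  # (nz,)
    angle_indices: np.ndarray  # (na,)
    cell_radius_um: np.ndarray  # (nz, na)
    cell_area_mm2: np.ndarray  # (nz, na)
    theta_step: float
    radial_spacing_um: float
    wraps: bool  # grid closes on itself in theta (full-circumference neck)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_area_mm2.shape

    @property
    def total_area_mm2(self) -> float:
        return float(self.cell_area_mm2.sum())


def build_neck_surface(annotation: WallAnnotation, geometry: AcquisitionGeometry) -> NeckSurface:
    """Reconstruct the neck surface from the annotation on the A-line grid.

    ``cell_area = (frame_pitch/1000) * (cell_radius/1000) * theta_step`` mm^2.
    """
    if not annotation.neck_angles:
        raise AnnotationError("annotation has no ostium angular interval")
    if len(annotation.neck_angles) > 1:
        raise AnnotationError("multiple ostium intervals per neck are not supported")
    n = int(geometry.n_alines)
    step = geometry.theta_step
    z0, z1 = annotation.neck_frames

    _, mask = interpolate_wall(annotation, z0, n)
    if not mask.any():
        raise AnnotationError("ostium interval selects no angular cells")

    idx = np.flatnonzero(mask)
    wraps = bool(mask.all())
    if not wraps and mask[0] and mask[-1]:
        # interval wraps across theta = 0: reorder columns to be contiguous
        breaks = np.flatnonzero(~mask)
        start = (breaks[-1] + 1) % n
        idx = np.array([(start + k) % n for k in range(int(mask.sum()))])

    nz = z1 - z0 + 1
    radius = np.empty((nz, idx.size))
    for i, z in enumerate(range(z0, z1 + 1)):
        r_all, m = interpolate_wall(annotation, z, n)
        if not np.array_equal(np.sort(np.flatnonzero(m)), np.sort(idx)):
            raise AnnotationError(f"frame {z}: ostium cells differ from frame {z0}")
        radius[i] = r_all[idx]
    if not np.all(radius > 0):
        raise AnnotationError("non-positive wall radius in neck region")

    pitch_mm = geometry.frame_pitch_um / 1000.0
    area = pitch_mm * (radius / 1000.0) * step
    return NeckSurface(
        frame_indices=np.arange(z0, z1 + 1),
        angle_indices=idx,
        cell_radius_um=radius,
        cell_area_mm2=area,
        theta_step=step,
        radial_spacing_um=geometry.radial_spacing_um,
        wraps=wraps,
    )
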