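"""Calibrated digital phantoms of device-treated aneurysm necks.

A phantom emulates an intravascular OCT pullback through a tubular vessel
with a saccular ostium (the aneurysm neck) spanned by a strut mesh that may
contain a designed uncovered gap.  Rendering, per frame and A-line:

* the vessel wall is a bright band at the vessel radius with exponential
  depth attenuation; it is absent over the ostium;
* metallic struts are thin saturated arcs at the ostium level, each trailing
  a *complete* (zero-signal) shadow to the frame edge — the defining optical
  property of metal.  Tissue never casts a complete shadow;
* the lumen is dark, with an optional uniform residual-blood haze emulating
  incomplete contrast clearing;
* multiplicative unit-mean gamma speckle (the standard first-order OCT
  speckle model) with configurable contrast, then clipping to the 16-bit
  ceiling (bright specular strut reflections saturate the detector).

Radial class edges are placed half a radial sample inside the nominal radius
and angular edges snap to polar-cell boundaries, so ground-truth labels are
exact on the sampling grid: the noise-free wall surface lands exactly at
sample ``round(R / radial_spacing)`` on every A-line.

Everything is deterministic given the seed, and every phantom ships with
ground-truth labels, the exact wall annotation, and the rasterised area of
the designed gap on the neck surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError, InputError
from .io import TWO_PI, AcquisitionGeometry, CaseRecord, OCTVolume, WallAnnotation
from .geometry import angle_in_interval
from .segmentation import CLOT_TISSUE, DEVICE, LUMEN

__all__ = [
    "StrutArc",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "gap_spec_for_area",
    "make_study_fixture",
]

INTENSITY_MAX = 65535


@dataclass(frozen=True)
class StrutArc:
    """One strut arc: frames [z_lo, z_hi] x angles [theta_lo, theta_hi)."""

    z_lo: int
    z_hi: int
    theta_lo: float
    theta_hi: float
    radial_offset_um: float = 0.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, device layout and noise of one phantom pullback.

    The default scale (256 A-lines x 128 radial samples x 60 frames, 10 um
    radial spacing, 100 um frame pitch, 1 mm vessel radius, 20-frame x 120
    degree ostium) is a reduced but fully calibrated stand-in for a real
    pullback; every dimension is configurable.
    """

    vessel_radius_um: float = 1000.0
    n_frames: int = 60
    n_alines: int = 256
    n_radii: int = 128
    radial_spacing_um: float = 10.0
    frame_pitch_um: float = 100.0
    ostium_frames: tuple[int, int] = (20, 39)
    ostium_angles: tuple[float, float] = (0.5, 0.5 + 2.0 * math.pi / 3.0)
    strut_pattern: tuple[StrutArc, ...] | None = None  # None -> auto mesh minus gap
    designed_gap: tuple[int, int, float, float] | None = None  # (z_lo, z_hi, t_lo, t_hi)
    tissue_level: float = 0.5  # of intensity_max, at the wall surface
    strut_level: float = 1.3  # pre-clip; >1 saturates (specular metal)
    attenuation_per_sample: float = 0.04
    strut_width_um: float = 30.0
    speckle_contrast: float = 0.3  # 0 disables speckle
    residual_blood_level: float = 0.0  # of intensity_max
    seed: int = 0

    def __post_init__(self):
        for name in ("vessel_radius_um", "radial_spacing_um", "frame_pitch_um", "strut_width_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_frames < 1 or self.n_alines < 8 or self.n_radii < 8:
            raise ConfigurationError("phantom grid too small")
        z0, z1 = self.ostium_frames
        if not (0 <= z0 <= z1 < self.n_frames):
            raise ConfigurationError(f"ostium frames {self.ostium_frames} outside volume")
        if not (0.0 <= self.speckle_contrast < 1.0):
            raise ConfigurationError("speckle_contrast must be in [0, 1)")
        if not (0.0 <= self.residual_blood_level < 1.0):
            raise ConfigurationError("residual_blood_level must be in [0, 1)")
        if self.vessel_radius_um / self.radial_spacing_um > self.n_radii - 4:
            raise ConfigurationError("vessel radius does not fit inside the radial field of view")
        if self.designed_gap is not None:
            gz0, gz1, gt0, gt1 = self.designed_gap
            if not (z0 <= gz0 <= gz1 <= z1):
                raise ConfigurationError("designed gap frames must lie inside the ostium")

    @property
    def theta_step(self) -> float:
        return TWO_PI / self.n_alines

    @property
    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            radial_spacing_um=self.radial_spacing_um,
            n_alines=self.n_alines,
            frame_pitch_um=self.frame_pitch_um,
            catheter_center_xy=None,
        )


@dataclass
class PhantomTruth:
    """Ground truth rendered from the same geometry, before noise."""

    labels: np.ndarray  # (n_frames, n_alines, n_radii) uint8
    true_gap_area_mm2: float
    gap_cells: list[tuple[int, int]]  # (frame, angle index) on the neck grid
    annotation: WallAnnotation
    wall_sample_index: int


def _snap_edge(theta: float, step: float) -> float:
    """Nearest polar-cell edge (cells are centred on k*step)."""
    m = round(theta / step - 0.5)
    return (m + 0.5) * step


def _auto_arcs(cfg: PhantomConfig, ostium: tuple[float, float]) -> list[StrutArc]:
    """Strut arcs tiling the ostium, leaving the designed gap strut-free."""
    z0, z1 = cfg.ostium_frames
    t0, t1 = ostium
    if cfg.designed_gap is None:
        return [StrutArc(z0, z1, t0, t1)]
    gz0, gz1, gt0, gt1 = cfg.designed_gap
    step = cfg.theta_step
    gt0, gt1 = _snap_edge(gt0, step), _snap_edge(gt1, step)
    arcs = []
    if gz0 > z0:
        arcs.append(StrutArc(z0, gz0 - 1, t0, t1))
    if gz1 < z1:
        arcs.append(StrutArc(gz1 + 1, z1, t0, t1))
    # frames containing the gap: cover the ostium on both sides of it
    width = (t1 - t0) % TWO_PI or TWO_PI
    if (gt0 - t0) % TWO_PI < width and (gt0 - t0) % TWO_PI > 1e-12:
        arcs.append(StrutArc(gz0, gz1, t0, gt0))
    if (gt1 - t0) % TWO_PI < width - 1e-12:
        arcs.append(StrutArc(gz0, gz1, gt1, t1))
    return arcs


def _make_annotation(cfg: PhantomConfig, ostium: tuple[float, float], n_points: int = 24) -> WallAnnotation:
    thetas = np.arange(n_points) * (TWO_PI / n_points)
    traces = {}
    for z in range(cfg.n_frames):
        if cfg.ostium_frames[0] <= z <= cfg.ostium_frames[1]:
            keep = ~angle_in_interval(thetas, ostium)
        else:
            keep = np.ones(n_points, dtype=bool)
        traces[z] = [(float(t), float(cfg.vessel_radius_um)) for t in thetas[keep]]
    return WallAnnotation(
        traces=traces, neck_frames=cfg.ostium_frames, neck_angles=[ostium]
    )


def generate_phantom(cfg: PhantomConfig) -> tuple[OCTVolume, PhantomTruth, WallAnnotation]:
    """Render one phantom pullback with its ground truth.

    Deterministic given ``cfg.seed``.
    """
    step = cfg.theta_step
    ostium = (_snap_edge(cfg.ostium_angles[0], step), _snap_edge(cfg.ostium_angles[1], step))
    if abs((ostium[1] - ostium[0]) % TWO_PI) < step / 2:
        raise ConfigurationError("ostium angular interval is empty after grid snapping")
    arcs = list(cfg.strut_pattern) if cfg.strut_pattern is not None else _auto_arcs(cfg, ostium)
    arcs = [
        replace(a, theta_lo=_snap_edge(a.theta_lo, step), theta_hi=_snap_edge(a.theta_hi, step))
        for a in arcs
    ]

    dr = cfg.radial_spacing_um
    size = 2 * cfg.n_radii + 1
    c = cfg.n_radii  # centre pixel (both axes)
    yy, xx = np.mgrid[0:size, 0:size]
    rho_um = np.hypot(xx - c, yy - c) * dr
    theta = np.arctan2(yy - c, xx - c) % TWO_PI

    edge_in = cfg.vessel_radius_um - dr / 2.0  # radial class edge (half-sample convention)
    in_ostium_ang = angle_in_interval(theta, ostium)
    oz0, oz1 = cfg.ostium_frames

    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((cfg.n_frames, size, size), dtype=np.uint16)
    wall_region = rho_um >= edge_in
    tissue_profile = cfg.tissue_level * np.exp(
        -cfg.attenuation_per_sample * (rho_um - edge_in) / dr
    )

    for z in range(cfg.n_frames):
        strut_ang = np.zeros_like(theta, dtype=bool)
        offsets = np.zeros_like(theta)
        for a in arcs:
            if a.z_lo <= z <= a.z_hi:
                m = angle_in_interval(theta, (a.theta_lo, a.theta_hi))
                strut_ang |= m
                offsets[m] = a.radial_offset_um
        wall_ang = ~(in_ostium_ang & (oz0 <= z <= oz1))

        img = np.zeros_like(theta)
        tis = wall_ang & ~strut_ang & wall_region
        img[tis] = tissue_profile[tis]
        if strut_ang.any():
            s_in = edge_in + offsets
            band = strut_ang & (rho_um >= s_in) & (rho_um < s_in + cfg.strut_width_um)
            img[band] = cfg.strut_level
        if cfg.residual_blood_level > 0:
            lumen = (img == 0) & (rho_um < edge_in)
            img[lumen] = cfg.residual_blood_level
        if cfg.speckle_contrast > 0:
            k = 1.0 / cfg.speckle_contrast**2
            img = img * rng.gamma(k, 1.0 / k, size=img.shape)
        np.clip(img, 0.0, 1.0, out=img)
        frames[z] = np.round(img * INTENSITY_MAX).astype(np.uint16)

    volume = OCTVolume(frames=frames, geometry=cfg.geometry, intensity_max=INTENSITY_MAX)

    truth = _render_truth(cfg, ostium, arcs)
    annotation = truth.annotation
    return volume, truth, annotation


def _render_truth(cfg: PhantomConfig, ostium, arcs) -> PhantomTruth:
    step = cfg.theta_step
    theta_k = np.arange(cfg.n_alines) * step
    W = int(round(cfg.vessel_radius_um / cfg.radial_spacing_um))
    # depth at which the rendered attenuation falls below the nominal tissue
    # floor (a quarter of the ceiling)
    depth = int(math.ceil(math.log(max(cfg.tissue_level, 0.25) / 0.25) / cfg.attenuation_per_sample))
    w_samples = max(1, int(round(cfg.strut_width_um / cfg.radial_spacing_um)))
    in_ostium = angle_in_interval(theta_k, ostium)
    oz0, oz1 = cfg.ostium_frames

    labels = np.full((cfg.n_frames, cfg.n_alines, cfg.n_radii), LUMEN, dtype=np.uint8)
    for z in range(cfg.n_frames):
        strut_ang = np.zeros(cfg.n_alines, dtype=bool)
        off = np.zeros(cfg.n_alines)
        for a in arcs:
            if a.z_lo <= z <= a.z_hi:
                m = angle_in_interval(theta_k, (a.theta_lo, a.theta_hi))
                strut_ang |= m
                off[m] = a.radial_offset_um
        wall_ang = ~(in_ostium & (oz0 <= z <= oz1))
        for t in np.flatnonzero(strut_ang):
            s = int(round((cfg.vessel_radius_um + off[t]) / cfg.radial_spacing_um))
            labels[z, t, s : min(s + w_samples, cfg.n_radii)] = DEVICE
        for t in np.flatnonzero(wall_ang & ~strut_ang):
            labels[z, t, W : min(W + depth, cfg.n_radii)] = CLOT_TISSUE

    gap_cells: list[tuple[int, int]] = []
    area = 0.0
    if cfg.designed_gap is not None:
        gz0, gz1, gt0, gt1 = cfg.designed_gap
        gt0, gt1 = _snap_edge(gt0, step), _snap_edge(gt1, step)
        cell_area = (cfg.frame_pitch_um / 1000.0) * (cfg.vessel_radius_um / 1000.0) * step
        in_gap = angle_in_interval(theta_k, (gt0, gt1)) & in_ostium
        for z in range(gz0, gz1 + 1):
            for t in np.flatnonzero(in_gap):
                gap_cells.append((z, int(t)))
        area = cell_area * len(gap_cells)

    return PhantomTruth(
        labels=labels,
        true_gap_area_mm2=area,
        gap_cells=gap_cells,
        annotation=_make_annotation(cfg, ostium),
        wall_sample_index=W,
    )


def gap_spec_for_area(cfg: PhantomConfig, area_mm2: float) -> tuple[int, int, float, float] | None:
    """A cell-aligned designed gap, centred in the ostium, of ~``area_mm2``.

    The gap is shaped roughly physically square (frame pitch vs arc length)
    and its edges snap to the polar cell grid, so the rasterised ground-truth
    area matches the request to within one cell row.  Returns ``None`` for a
    zero-area request (fully covered neck).
    """
    if area_mm2 < 0:
        raise InputError(f"gap area must be >= 0, got {area_mm2}")
    if area_mm2 == 0:
        return None
    step = cfg.theta_step
    t0 = _snap_edge(cfg.ostium_angles[0], step)
    t1 = _snap_edge(cfg.ostium_angles[1], step)
    o_steps = int(round(((t1 - t0) % TWO_PI) / step))
    z0, z1 = cfg.ostium_frames
    o_nz = z1 - z0 + 1

    pitch_mm = cfg.frame_pitch_um / 1000.0
    arc_mm = (cfg.vessel_radius_um / 1000.0) * step
    cell_area = pitch_mm * arc_mm
    n_cells = max(1, round(area_mm2 / cell_area))
    n_gf = int(np.clip(round(math.sqrt(n_cells * arc_mm / pitch_mm)), 1, o_nz))
    n_steps = int(np.clip(round(n_cells / n_gf), 1, o_steps))
    if n_gf * n_steps * cell_area < 0.5 * area_mm2:
        raise ConfigurationError(
            f"requested gap of {area_mm2} mm^2 does not fit inside the ostium "
            f"({o_nz} frames x {o_steps} angle steps)"
        )
    gz0 = z0 + (o_nz - n_gf) // 2
    gt0 = t0 + ((o_steps - n_steps) // 2) * step
    return (gz0, gz0 + n_gf - 1, gt0, gt0 + n_steps * step)


def make_study_fixture(
    gap_areas_mm2: list[float],
    seed: int = 0,
    n_cases: int | None = None,
    base_config: PhantomConfig | None = None,
) -> list[tuple[OCTVolume, PhantomTruth, CaseRecord]]:
    """One phantom per requested gap area, with a matching case record.

    The record's 180-day outcome emulates the observed association: residual
    filling (grade 3) iff the designed gap exceeds 1 mm^2, else occluded
    (grade 1).  The record's ``largest_gap_mm2`` is the rasterised truth area.
    """
    if n_cases is None:
        n_cases = len(gap_areas_mm2)
    if n_cases != len(gap_areas_mm2):
        raise InputError("n_cases must match the number of requested gap areas")
    if any(a < 0 for a in gap_areas_mm2):
        raise InputError("gap areas must be >= 0")
    base = base_config or PhantomConfig()
    out = []
    for i, area in enumerate(gap_areas_mm2):
        cfg = replace(base, designed_gap=gap_spec_for_area(base, area), seed=seed + i)
        volume, truth, _ = generate_phantom(cfg)
        record = CaseRecord(
            animal_id=f"P{i + 1}",
            location="bifurcation",
            device="NGID",
            n_implants=1,
            herniation=False,
            largest_gap_mm2=truth.true_gap_area_mm2,
            dsa_implant=3,
            dsa_180d=3 if area > 1.0 else 1,
        )
        out.append((volume, truth, record))
    return out
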