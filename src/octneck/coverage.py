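"""Neck-coverage mapping, gap measurement and the 1 mm^2 occlusion rule.

Device labels are projected onto the reconstructed neck surface: a neck cell
is *covered* when a DEVICE pixel lies within a radial band about the wall
radius along that cell's A-line.  Connected uncovered regions (8-connected,
wrapping in the angular direction for full-circumference necks, never across
frames beyond +-1) are the coverage gaps; the largest gap area in mm^2 feeds
the prediction rule: a gap strictly larger than the threshold (default
1 mm^2) predicts residual aneurysm filling at follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .exceptions import InputError
from .geometry import NeckSurface
from .segmentation import CLOT_TISSUE, DEVICE, LabelVolume

__all__ = [
    "Occlusion",
    "CoverageMap",
    "Gap",
    "build_coverage_map",
    "find_gaps",
    "largest_gap_area",
    "predict_occlusion",
    "coverage_summary",
    "write_coverage_csv",
]


class Occlusion(str, Enum):
    OCCLUDED = "OCCLUDED"
    RESIDUAL = "RESIDUAL"


@dataclass
class CoverageMap:
    """Covered/uncovered state of every neck-surface cell."""

    covered: np.ndarray  # bool, shape == neck.shape
    neck: NeckSurface
    covering_classes: tuple[int, ...]  # label classes that count as covering
    band_halfwidth_um: float

    def __post_init__(self):
        if self.covered.shape != self.neck.shape:
            raise InputError(
                f"coverage grid {self.covered.shape} does not match neck grid {self.neck.shape}"
            )

    @property
    def covered_fraction(self) -> float:
        """Area-weighted fraction of the neck surface that is covered."""
        total = self.neck.cell_area_mm2.sum()
        return float(self.neck.cell_area_mm2[self.covered].sum() / total)


@dataclass
class Gap:
    """One connected uncovered region of the neck surface."""

    cells: list[tuple[int, int]]  # (frame_index, angle_index), global indices
    area_mm2: float
    frame_extent: tuple[int, int]  # inclusive frame range
    angular_extent_rad: float


def build_coverage_map(
    labels: LabelVolume,
    neck: NeckSurface,
    band_halfwidth_um: float = 100.0,
    include_tissue: bool = False,
) -> CoverageMap:
    """Project device labels onto the neck surface.

    A cell (z, theta) is covered iff any DEVICE pixel (also CLOT_TISSUE when
    ``include_tissue`` — for follow-up timepoints where neointima counts as
    coverage) lies within ``+-band_halfwidth_um`` of the wall radius along
    A-line theta of frame z.
    """
    if abs(labels.radial_spacing_um - neck.radial_spacing_um) > 1e-9:
        raise InputError("label volume and neck surface disagree on radial spacing")
    if labels.labels.shape[1] != round(2 * np.pi / neck.theta_step):
        raise InputError("label volume and neck surface disagree on the angular grid")
    nz, na = neck.shape
    n_radii = labels.labels.shape[2]
    band = int(round(band_halfwidth_um / neck.radial_spacing_um))
    classes = (DEVICE, CLOT_TISSUE) if include_tissue else (DEVICE,)

    covered = np.zeros((nz, na), dtype=bool)
    for i, z in enumerate(neck.frame_indices):
        if not (0 <= z < labels.n_frames):
            raise InputError(f"neck frame {z} outside label volume of {labels.n_frames} frames")
        for j, t in enumerate(neck.angle_indices):
            ri = int(round(neck.cell_radius_um[i, j] / neck.radial_spacing_um))
            lo, hi = max(ri - band, 0), min(ri + band + 1, n_radii)
            window = labels.labels[z, t, lo:hi]
            covered[i, j] = bool(np.isin(window, classes).any())
    return CoverageMap(
        covered=covered, neck=neck, covering_classes=classes, band_halfwidth_um=band_halfwidth_um
    )


def _connected_components(uncovered: np.ndarray, wraps: bool) -> np.ndarray:
    """8-connected labelling of uncovered cells, wrapping columns when asked."""
    structure = np.ones((3, 3), dtype=bool)
    lab, n = ndimage.label(uncovered, structure=structure)
    if wraps and uncovered.shape[1] > 1 and n > 1:
        # merge components touching across the theta seam (rows within +-1)
        parent = list(range(n + 1))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        left, right = lab[:, 0], lab[:, -1]
        nz = lab.shape[0]
        for i in range(nz):
            if left[i] == 0:
                continue
            for di in (-1, 0, 1):
                k = i + di
                if 0 <= k < nz and right[k] != 0:
                    union(left[i], right[k])
        lab = np.array([[find(v) if v else 0 for v in row] for row in lab])
    return lab


def find_gaps(cov: CoverageMap) -> list[Gap]:
    """All coverage gaps, sorted by area descending (ties: first occurrence)."""
    uncovered = ~cov.covered
    if not uncovered.any():
        return []
    lab = _connected_components(uncovered, cov.neck.wraps)
    neck = cov.neck
    gaps = []
    for comp in np.unique(lab):
        if comp == 0:
            continue
        ii, jj = np.nonzero(lab == comp)
        area = float(neck.cell_area_mm2[ii, jj].sum())
        frames = neck.frame_indices[ii]
        gaps.append(
            Gap(
                cells=[(int(neck.frame_indices[i]), int(neck.angle_indices[j])) for i, j in zip(ii, jj)],
                area_mm2=area,
                frame_extent=(int(frames.min()), int(frames.max())),
                angular_extent_rad=float((jj.max() - jj.min() + 1) * neck.theta_step),
            )
        )
    gaps.sort(key=lambda g: -g.area_mm2)
    return gaps


def largest_gap_area(cov: CoverageMap) -> float:
    """Area of the largest coverage gap, 0 when the neck is fully covered."""
    gaps = find_gaps(cov)
    return gaps[0].area_mm2 if gaps else 0.0


def predict_occlusion(largest_gap_mm2: float, threshold_mm2: float = 1.0) -> Occlusion:
    """Dichotomous outcome prediction from the largest neck-coverage gap.

    RESIDUAL iff the gap is *strictly* larger than the threshold; a gap of
    exactly the threshold area predicts occlusion.
    """
    if largest_gap_mm2 < 0:
        raise InputError(f"gap area must be >= 0, got {largest_gap_mm2}")
    return Occlusion.RESIDUAL if largest_gap_mm2 > threshold_mm2 else Occlusion.OCCLUDED


def coverage_summary(cov: CoverageMap) -> dict:
    """JSON-ready summary: total area, covered fraction, per-gap areas/extents."""
    gaps = find_gaps(cov)
    return {
        "total_area_mm2": cov.neck.total_area_mm2,
        "covered_fraction": cov.covered_fraction,
        "band_halfwidth_um": cov.band_halfwidth_um,
        "gaps": [
            {
                "area_mm2": g.area_mm2,
                "frame_extent": list(g.frame_extent),
                "angular_extent_rad": g.angular_extent_rad,
                "n_cells": len(g.cells),
            }
            for g in gaps
        ],
    }


def write_coverage_csv(cov: CoverageMap, path) -> None:
    """Covered grid as CSV: rows = neck frames, columns = angle steps, values 0/1."""
    header = ",".join(str(int(t)) for t in cov.neck.angle_indices)
    rows = [f"frame_{int(z)}," + ",".join(str(int(v)) for v in row)
            for z, row in zip(cov.neck.frame_indices, cov.covered.astype(int))]
    with open(path, "w") as fh:
        fh.write("frame," + header + "\n")
        fh.write("\n".join(rows) + "\n")


def write_gap_json(cov: CoverageMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(coverage_summary(cov), fh, indent=1, sort_keys=True)
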