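"""Three-class per-pixel segmentation of polar HF-OCT frames.

Every pixel of an A-line is assigned one of three classes: LUMEN, CLOT_TISSUE
or DEVICE.  The classifier is a deterministic rule cascade built from four
cues: the local intensity gradient, a signal threshold, the complete shadow
trailed by metallic struts (which fully block the near-infrared beam), and
the cumulative signal sum from the catheter centre outward.

Cascade, per A-line:

1. *Surface*: the smallest radius where the moving-average-smoothed gradient
   exceeds ``surface_gradient_min``, the raw intensity exceeds
   ``tissue_intensity_min``, and the cumulative sum up to (but excluding) that
   radius is at most ``cumsum_lumen_max`` of the A-line total.  Everything
   proximal to the surface is lumen; an A-line with no surface is all lumen.
2. *Strut vs tissue*: when a sample within a short standoff window after the
   surface (``strut_standoff_samples``, allowing for partial-volume blur at
   the strut's leading edge) exceeds ``device_intensity_min`` and the run
   distal to the bright run is a complete shadow, the bright run is a
   metallic strut and is labelled DEVICE; the shadow itself is labelled LUMEN
   (it is signal void, so uncleared-blood artifacts cannot masquerade as
   coverage).
3. *Tissue*: otherwise the surface and distal pixels are CLOT_TISSUE until
   the smoothed intensity attenuates below ``tissue_intensity_min``.

All thresholds are fractions of the normalisation ceiling ``intensity_max``
(the gradient threshold is per radial sample).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, InputError
from .geometry import PolarFrame, cartesian_to_polar
from .io import OCTVolume

__all__ = [
    "LUMEN",
    "CLOT_TISSUE",
    "DEVICE",
    "SegmentationParams",
    "LabelMap",
    "LabelVolume",
    "detect_surface",
    "detect_shadow",
    "classify_frame",
    "classify_volume",
]

LUMEN = 0
CLOT_TISSUE = 1
DEVICE = 2


@dataclass(frozen=True)
class SegmentationParams:
    """Classifier thresholds, all as fractions of ``intensity_max``.

    Defaults were tuned on phantoms; the prototype system publishes none.
    """

    surface_gradient_min: float = 0.05  # per radial sample
    device_intensity_min: float = 0.6
    tissue_intensity_min: float = 0.25
    shadow_ratio_max: float = 0.1  # of the strut peak
    shadow_noise_floor: float = 0.05
    cumsum_lumen_max: float = 0.15  # of the per-A-line total
    smoothing_halfwidth: int = 2  # samples
    strut_max_samples: int = 10  # ~100 um at 10 um spacing
    strut_standoff_samples: int = 2  # surface-to-strut-peak leeway

    def __post_init__(self):
        fracs = {
            "surface_gradient_min": self.surface_gradient_min,
            "device_intensity_min": self.device_intensity_min,
            "tissue_intensity_min": self.tissue_intensity_min,
            "shadow_ratio_max": self.shadow_ratio_max,
            "shadow_noise_floor": self.shadow_noise_floor,
            "cumsum_lumen_max": self.cumsum_lumen_max,
        }
        for name, v in fracs.items():
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.device_intensity_min <= self.tissue_intensity_min:
            raise ConfigurationError("device_intensity_min must exceed tissue_intensity_min")
        if self.smoothing_halfwidth < 0 or self.strut_max_samples < 1:
            raise ConfigurationError("invalid smoothing_halfwidth or strut_max_samples")
        if self.strut_standoff_samples < 0:
            raise ConfigurationError("strut_standoff_samples must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationParams":
        return cls(**d)


@dataclass
class LabelMap:
    """Per-pixel labels for one polar frame, plus per-A-line surface/shadows."""

    labels: np.ndarray  # (n_angles, n_radii) uint8
    surface_index: np.ndarray  # (n_angles,) int, -1 where no surface
    shadow_intervals: list[tuple[int, int, int]]  # (aline, start, stop)
    theta_step: float
    radial_spacing_um: float


@dataclass
class LabelVolume:
    """Stacked per-frame labels for a whole pullback."""

    labels: np.ndarray  # (n_frames, n_angles, n_radii) uint8
    surface_index: np.ndarray  # (n_frames, n_angles) int
    theta_step: float
    radial_spacing_um: float

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


def _smooth(profile: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth == 0:
        return profile.astype(float)
    return ndimage.uniform_filter1d(profile.astype(float), size=2 * halfwidth + 1,
                                    axis=-1, mode="nearest")


def detect_surface(aline: np.ndarray, params: SegmentationParams, intensity_max: float) -> int | None:
    """First sample satisfying the gradient + signal + cumulative-sum cues.

    Returns ``None`` when no sample qualifies (e.g. an all-dark A-line).
    """
    aline = np.asarray(aline, dtype=float)
    if aline.size == 0:
        raise InputError("empty A-line")
    if aline.size < 2 * params.smoothing_halfwidth + 1:
        raise InputError(
            f"A-line of {aline.size} samples too short for smoothing halfwidth "
            f"{params.smoothing_halfwidth}"
        )
    idx = _surface_indices(aline[None, :], params, intensity_max)[0]
    return None if idx < 0 else int(idx)


def _surface_indices(alines: np.ndarray, params: SegmentationParams, intensity_max: float) -> np.ndarray:
    """Vectorised surface detection over a (n_alines, n_radii) block."""
    smooth = _smooth(alines, params.smoothing_halfwidth)
    grad = np.gradient(smooth, axis=-1)
    total = alines.sum(axis=-1, keepdims=True)
    cum_before = np.concatenate(
        [np.zeros_like(alines[..., :1]), np.cumsum(alines, axis=-1)[..., :-1]], axis=-1
    )
    cond = (
        (grad >= params.surface_gradient_min * intensity_max)
        & (alines >= params.tissue_intensity_min * intensity_max)
        & (cum_before <= params.cumsum_lumen_max * total)
    )
    has = cond.any(axis=-1)
    idx = np.where(has, cond.argmax(axis=-1), -1)
    return idx.astype(np.int64)


def _strut_run_length(aline: np.ndarray, start: int, params: SegmentationParams,
                      intensity_max: float) -> int:
    """Contiguous run >= device_intensity_min from ``start``, capped at strut_max_samples."""
    thr = params.device_intensity_min * intensity_max
    n = aline.size
    w = 0
    while start + w < n and w < params.strut_max_samples and aline[start + w] >= thr:
        w += 1
    return max(w, 1)


def detect_shadow(
    aline: np.ndarray,
    strut_index: int,
    params: SegmentationParams,
    intensity_max: float,
) -> tuple[bool, tuple[int, int]]:
    """Is the run distal to a strut a *complete* shadow?

    The interval distal to the strut's bright run counts as a complete shadow
    when its mean intensity is at most ``max(shadow_ratio_max * strut peak,
    shadow_noise_floor * intensity_max)``.  Returns ``(is_shadow, (start,
    stop))``; an empty distal interval (strut at the A-line end) is vacuously
    a shadow.
    """
    aline = np.asarray(aline, dtype=float)
    if not (0 <= strut_index < aline.size):
        raise InputError(f"strut_index {strut_index} out of range for {aline.size} samples")
    if aline[strut_index] < params.device_intensity_min * intensity_max:
        raise InputError("strut_index does not point at a device-bright surface")
    w = _strut_run_length(aline, strut_index, params, intensity_max)
    start, stop = strut_index + w, aline.size
    peak = float(aline[strut_index:stop if w == 0 else strut_index + w].max())
    threshold = max(params.shadow_ratio_max * peak, params.shadow_noise_floor * intensity_max)
    tail = aline[start:stop]
    is_shadow = True if tail.size == 0 else bool(tail.mean() <= threshold)
    return is_shadow, (start, stop)


def classify_frame(polar: PolarFrame, params: SegmentationParams, intensity_max: float) -> LabelMap:
    """Classify every pixel of one polar frame (see module docstring)."""
    alines = np.asarray(polar.alines, dtype=float)
    n_ang, n_rad = alines.shape
    if n_rad < 2 * params.smoothing_halfwidth + 1:
        raise InputError("frame has too few radial samples for the smoothing window")

    surf = _surface_indices(alines, params, intensity_max)
    labels = np.zeros((n_ang, n_rad), dtype=np.uint8)
    shadows: list[tuple[int, int, int]] = []

    smooth = _smooth(alines, params.smoothing_halfwidth)
    cols = np.arange(n_rad)[None, :]
    surfaced = surf >= 0
    s_col = np.where(surfaced, surf, n_rad)[:, None]

    # tissue extent: first sample after the surface where the smoothed
    # intensity has attenuated below the tissue threshold; the search starts
    # past the smoothing window so dark lumen samples proximal to the surface
    # cannot drag the smoothed value down and truncate the band
    below = smooth < params.tissue_intensity_min * intensity_max
    below_after = below & (cols >= s_col + params.smoothing_halfwidth + 1)
    has_end = below_after.any(axis=1)
    t_end = np.where(has_end, below_after.argmax(axis=1), n_rad)
    t_end = np.maximum(t_end, surf + 1)  # surface pixel itself is never lumen

    dev_thr = params.device_intensity_min * intensity_max
    for i in np.flatnonzero(surfaced):
        s = int(surf[i])
        window = alines[i, s : min(s + params.strut_standoff_samples + 1, n_rad)]
        bright = np.flatnonzero(window >= dev_thr)
        if bright.size:
            b0 = s + int(bright[0])  # leading edge of the strut's bright run
            is_shadow, interval = detect_shadow(alines[i], b0, params, intensity_max)
            if is_shadow:
                w = _strut_run_length(alines[i], b0, params, intensity_max)
                labels[i, b0 : b0 + w] = DEVICE
                if b0 > s:
                    labels[i, s:b0] = LUMEN
                shadows.append((i, interval[0], interval[1]))
                continue
        labels[i, s : int(t_end[i])] = CLOT_TISSUE

    return LabelMap(
        labels=labels,
        surface_index=surf,
        shadow_intervals=shadows,
        theta_step=polar.theta_step,
        radial_spacing_um=polar.radial_spacing_um,
    )


def classify_volume(
    volume: OCTVolume,
    params: SegmentationParams | None = None,
    centers: np.ndarray | None = None,
    n_radii: int | None = None,
) -> LabelVolume:
    """Remap every frame to polar coordinates and classify it.

    ``centers`` is an optional (n_frames, 2) array of per-frame catheter
    centres (x, y); by default the volume's constant centre is used.
    ``n_radii`` defaults to half the smaller frame dimension.
    """
    params = params or SegmentationParams()
    geom = volume.geometry
    if n_radii is None:
        n_radii = min(volume.frame_shape) // 2
    if centers is not None:
        centers = np.asarray(centers, dtype=float)
        if centers.shape != (volume.n_frames, 2):
            raise InputError(
                f"centers must have shape ({volume.n_frames}, 2), got {centers.shape}"
            )

    labels = np.zeros((volume.n_frames, geom.n_alines, n_radii), dtype=np.uint8)
    surface = np.full((volume.n_frames, geom.n_alines), -1, dtype=np.int64)
    theta_step = geom.theta_step
    for z in range(volume.n_frames):
        center = tuple(centers[z]) if centers is not None else volume.center_for_frame(z)
        polar = cartesian_to_polar(
            volume.frames[z], center, geom.n_alines, n_radii, geom.radial_spacing_um
        )
        lm = classify_frame(polar, params, volume.intensity_max)
        labels[z] = lm.labels
        surface[z] = lm.surface_index
    return LabelVolume(
        labels=labels,
        surface_index=surface,
        theta_step=theta_step,
        radial_spacing_um=geom.radial_spacing_um,
    )
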