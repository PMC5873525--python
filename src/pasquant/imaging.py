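"""Segmentation of calibrated grayscale micrographs into particle tables.

Bright particles on a dark background are thresholded (Renyi-entropy or
triangle method), labelled as 8-connected components, sized in calibrated
micrometres, and filtered by the area and edge-exclusion rules used for
passive sampler micrograph analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.filters import threshold_triangle as _skimage_triangle
from skimage.measure import label as _label
from skimage.measure import regionprops as _regionprops

DEFAULT_MAX_AREA_UM2 = 10_000.0

PARTICLE_COLUMNS = [
    "image_id",
    "particle_id",
    "area_um2",
    "d_pa_um",
    "x_um",
    "y_um",
    "touches_edge",
]


@dataclass(frozen=True)
class ImageCalibration:
    """Pixel scale and field-of-view of a micrograph.

    The study values are 1.71 px/um at x500 (450 um x 600 um field) and
    14.3 px/um at x3000.
    """

    pixels_per_micron: float = 1.71
    image_width_um: float = 450.0
    image_height_um: float = 600.0

    def __post_init__(self) -> None:
        if min(self.pixels_per_micron, self.image_width_um, self.image_height_um) <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixels_per_micron**-2

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered/acquired image in pixels."""
        return (
            int(round(self.image_height_um * self.pixels_per_micron)),
            int(round(self.image_width_um * self.pixels_per_micron)),
        )


@dataclass(frozen=True)
class ParticleObservation:
    """One segmented particle."""

    particle_id: int
    projected_area_um2: float
    centroid_x_um: float
    centroid_y_um: float
    touches_edge: bool
    source_image: str = ""

    def __post_init__(self) -> None:
        if self.projected_area_um2 <= 0:
            raise ValueError("projected area must be positive")

    @property
    def d_pa_um(self) -> float:
        """Diameter of the circle with the same projected area."""
        return 2.0 * np.sqrt(self.projected_area_um2 / np.pi)


@dataclass(frozen=True)
class FilterRules:
    """Inclusion rules for segmented particles.

    ``min_area_um2`` defaults to one pixel at the given calibration;
    ``max_area_um2`` removes objects too large to have passed the mesh cap;
    ``exclude_edge`` drops components touching the image border.
    """

    min_area_um2: float
    max_area_um2: float = DEFAULT_MAX_AREA_UM2
    exclude_edge: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("require 0 < min_area < max_area")

    @classmethod
    def for_calibration(cls, calib: ImageCalibration, **kwargs) -> "FilterRules":
        return cls(min_area_um2=calib.pixel_area_um2, **kwargs)


def _normalized_histogram(image: np.ndarray, nbins: int = 256):
    hist, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return hist.astype(float), centers


def renyi_entropy_threshold(image: np.ndarray, alpha: float = 1.0, nbins: int = 256) -> float:
    """Threshold maximizing the summed Renyi entropies of the two classes.

    For each candidate threshold t the histogram is split into background
    (<= t) and foreground (> t); each class is renormalized and its Renyi
    entropy of order ``alpha`` computed, H = log(sum p**alpha) / (1-alpha),
    with the alpha -> 1 limit giving the Shannon (maximum-entropy) case.
    Returns the gray value whose split maximizes H_b + H_f.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    hist, centers = _normalized_histogram(image, nbins)
    p = hist / hist.sum()
    cum = np.cumsum(p)
    best_value, best_obj = None, -np.inf
    for t in range(len(p) - 1):
        w_b, w_f = cum[t], 1.0 - cum[t]
        if w_b <= 0 or w_f <= 0:
            continue
        pb = p[: t + 1] / w_b
        pf = p[t + 1 :] / w_f
        if abs(alpha - 1.0) < 1e-12:
            with np.errstate(divide="ignore", invalid="ignore"):
                hb = -np.nansum(np.where(pb > 0, pb * np.log(pb), 0.0))
                hf = -np.nansum(np.where(pf > 0, pf * np.log(pf), 0.0))
        else:
            hb = np.log(np.sum(pb[pb > 0] ** alpha)) / (1.0 - alpha)
            hf = np.log(np.sum(pf[pf > 0] ** alpha)) / (1.0 - alpha)
        if hb + hf > best_obj:
            best_obj = hb + hf
            best_value = centers[t]
    if best_value is None:  # constant image; caller handles the warning
        raise ValueError("no threshold defined for a constant image")
    return float(best_value)


def find_threshold(image: np.ndarray, method: str = "renyi_entropy", alpha: float = 1.0) -> float:
    """Return the threshold gray value for ``method``.

    Raises ValueError for a constant image (no threshold is defined).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if image.min() == image.max():
        raise ValueError("no threshold defined for a constant image")
    if method == "renyi_entropy":
        return renyi_entropy_threshold(image, alpha=alpha)
    if method == "triangle":
        return float(_skimage_triangle(image))
    raise ValueError(f"unknown threshold method {method!r}")


def threshold_image(
    image: np.ndarray, method: str = "renyi_entropy", alpha: float = 1.0
) -> np.ndarray:
    """Binary particle mask (foreground = bright pixels above threshold).

    A constant image yields an all-background mask with a warning.
    """
    image = np.asarray(image)
    try:
        thresh = find_threshold(image, method=method, alpha=alpha)
    except ValueError as exc:
        if "constant" in str(exc):
            warnings.warn("constant image: returning empty mask", stacklevel=2)
            return np.zeros(image.shape, dtype=bool)
        raise
    return image > thresh


def extract_particles(
    mask: np.ndarray,
    calib: ImageCalibration,
    source_image: str = "",
    connectivity: int = 2,
) -> list[ParticleObservation]:
    """Label connected components of ``mask`` and size them in um.

    Component area is the integer pixel count divided by the square of the
    pixel density (no sub-pixel refinement); ``touches_edge`` is set when
    any component pixel lies on the image border.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _label(mask, connectivity=connectivity)
    nrows, ncols = mask.shape
    scale = 1.0 / calib.pixels_per_micron
    out: list[ParticleObservation] = []
    for prop in _regionprops(labels):
        minr, minc, maxr, maxc = prop.bbox
        touches = minr == 0 or minc == 0 or maxr == nrows or maxc == ncols
        cy, cx = prop.centroid  # (row, col)
        out.append(
            ParticleObservation(
                particle_id=int(prop.label),
                projected_area_um2=float(prop.area) * scale**2,
                centroid_x_um=cx * scale,
                centroid_y_um=cy * scale,
                touches_edge=bool(touches),
                source_image=source_image,
            )
        )
    return out


def filter_particles(
    particles: list[ParticleObservation], rules: FilterRules
) -> list[ParticleObservation]:
    """Apply the area and edge rules; order-preserving and idempotent."""
    kept = []
    for p in particles:
        if p.projected_area_um2 < rules.min_area_um2:
            continue
        if p.projected_area_um2 > rules.max_area_um2:
            continue
        if rules.exclude_edge and p.touches_edge:
            continue
        kept.append(p)
    return kept


def exclusion_reasons(
    particles: list[ParticleObservation], rules: FilterRules
) -> list[str]:
    """Audit column: empty string for retained particles, else the rule hit."""
    reasons = []
    for p in particles:
        if p.projected_area_um2 < rules.min_area_um2:
            reasons.append("below_min_area")
        elif p.projected_area_um2 > rules.max_area_um2:
            reasons.append("above_max_area")
        elif rules.exclude_edge and p.touches_edge:
            reasons.append("touches_edge")
        else:
            reasons.append("")
    return reasons


def edge_exclusion_fraction(d_um: float, calib: ImageCalibration) -> float:
    """Probability that a circle of diameter ``d_um``, placed uniformly in
    the image, touches an edge: 1 - (W-d)(H-d)/(W*H)."""
    w, h = calib.image_width_um, calib.image_height_um
    if d_um < 0 or d_um >= min(w, h):
        raise ValueError("diameter must satisfy 0 <= d < min(width, height)")
    return 1.0 - (w - d_um) * (h - d_um) / (w * h)


def particles_to_frame(
    particles: list[ParticleObservation],
    rules: FilterRules | None = None,
) -> pd.DataFrame:
    """Particle table in the pipeline CSV schema.

    With ``rules`` given, all particles are listed and an
    ``exclusion_reason`` audit column is added; otherwise the table holds
    exactly the given particles.
    """
    rows = {
        "image_id": [p.source_image for p in particles],
        "particle_id": [p.particle_id for p in particles],
        "area_um2": [p.projected_area_um2 for p in particles],
        "d_pa_um": [p.d_pa_um for p in particles],
        "x_um": [p.centroid_x_um for p in particles],
        "y_um": [p.centroid_y_um for p in particles],
        "touches_edge": [p.touches_edge for p in particles],
    }
    frame = pd.DataFrame(rows, columns=PARTICLE_COLUMNS)
    if rules is not None:
        frame["exclusion_reason"] = exclusion_reasons(particles, rules)
    return frame


def frame_to_particles(frame: pd.DataFrame) -> list[ParticleObservation]:
    """Inverse of :func:`particles_to_frame` (audit column ignored)."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            ParticleObservation(
                particle_id=int(row.particle_id),
                projected_area_um2=float(row.area_um2),
                centroid_x_um=float(row.x_um),
                centroid_y_um=float(row.y_um),
                touches_edge=bool(row.touches_edge),
                source_image=str(row.image_id),
            )
        )
    return out
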