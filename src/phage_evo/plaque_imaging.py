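"""Plate-photo plaque quantification.

Reimplements the classic particle-analysis workflow for plaque plates:
scale calibration against the known plate diameter, rolling-ball background
subtraction, dual-intensity thresholding inside an elliptical analysis
region, connected-component particle extraction with area and circularity
filters, and per-sample size statistics with pairwise comparisons.

Plaques are assumed *brighter* than the lawn (bright-field
transillumination of clearings); the synthetic renderer in
:mod:`phage_evo.synthetic_data` conforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage import measure
from skimage.restoration import rolling_ball

from .adsorption import compare_groups, holm_bonferroni, summarize_replicates


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the plaque pipeline, with the protocol defaults."""

    rolling_ball_radius_px: float = 50.0
    threshold_lower: float = 180.0
    threshold_upper: float = 238.0
    area_range_mm2: tuple[float, float] = (0.2, 64.0)
    circularity_range: tuple[float, float] = (0.20, 1.00)
    plate_diameter_mm: float = 86.0
    roi_diameter_mm: float = 72.24

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("area_range_mm2", "circularity_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class PlaqueMeasurement:
    area_mm2: float
    equivalent_diameter_mm: float
    perimeter_mm: float
    circularity: float
    centroid_mm: tuple[float, float]  # (x, y)


def load_image_grayscale(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF (RGB accepted) as 8-bit grayscale by luminance."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def calibrate_scale(
    measured_plate_diameter_px: float, plate_diameter_mm: float = 86.0
) -> float:
    """mm per pixel from the apparent plate diameter."""
    if measured_plate_diameter_px <= 0 or plate_diameter_mm <= 0:
        raise ValueError("plate diameters must be positive")
    return plate_diameter_mm / measured_plate_diameter_px


def subtract_background(image: np.ndarray, rolling_ball_radius_px: float = 50.0) -> np.ndarray:
    """Rolling-ball background subtraction, output clipped to 0-255 uint8.

    The background is the envelope traced by a ball of the given radius
    rolling under the intensity surface (morphological opening by a ball);
    a flat image maps to all zeros.
    """
    if rolling_ball_radius_px <= 0:
        raise ValueError("rolling-ball radius must be positive")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    background = rolling_ball(img.astype(float), radius=rolling_ball_radius_px)
    return np.clip(img.astype(float) - background, 0, 255).astype(np.uint8)


def elliptical_roi_mask(
    shape: tuple[int, int],
    mm_per_px: float,
    roi_diameter_mm: float = 72.24,
    roi_height_mm: Optional[float] = None,
    center_px: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Boolean mask of a centred ellipse (width x height in mm)."""
    h, w = shape
    height_mm = roi_height_mm if roi_height_mm is not None else roi_diameter_mm
    cy, cx = center_px if center_px is not None else ((h - 1) / 2, (w - 1) / 2)
    ry = height_mm / 2 / mm_per_px
    rx = roi_diameter_mm / 2 / mm_per_px
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def apply_threshold(
    image: np.ndarray,
    lower: float = 180.0,
    upper: float = 238.0,
    roi: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Select pixels with ``lower <= value <= upper``, masked to the ROI."""
    if not 0 <= lower <= upper <= 255:
        raise ValueError(f"need 0 <= lower <= upper <= 255, got {lower}, {upper}")
    mask = (image >= lower) & (image <= upper)
    if roi is not None:
        mask &= roi
    return mask


def analyze_particles(
    mask: np.ndarray,
    mm_per_px: float,
    area_range_mm2: tuple[float, float] = (0.2, 64.0),
    circularity_range: tuple[float, float] = (0.20, 1.00),
    roi: Optional[np.ndarray] = None,
) -> list[PlaqueMeasurement]:
    """Connected components (8-connectivity) filtered by area and circularity.

    Circularity is ``4*pi*A / P**2`` with the contour-traced perimeter,
    capped at 1.0 to absorb discretisation overshoot. Components touching
    the ROI boundary (or the image border) are discarded as truncated.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    labels = measure.label(mask, connectivity=2)
    border = _boundary_exclusion_zone(mask.shape, roi)
    out = []
    for region in measure.regionprops(labels):
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if border[rr, cc].any():
            continue
        area = region.area * mm_per_px**2
        perimeter = region.perimeter * mm_per_px
        if perimeter == 0:
            continue
        circularity = min(1.0, 4 * math.pi * area / perimeter**2)
        if not area_range_mm2[0] <= area <= area_range_mm2[1]:
            continue
        if not circularity_range[0] <= circularity <= circularity_range[1]:
            continue
        cy, cx = region.centroid
        out.append(
            PlaqueMeasurement(
                area_mm2=area,
                equivalent_diameter_mm=2 * math.sqrt(area / math.pi),
                perimeter_mm=perimeter,
                circularity=circularity,
                centroid_mm=(cx * mm_per_px, cy * mm_per_px),
            )
        )
    return out


def _boundary_exclusion_zone(
    shape: tuple[int, int], roi: Optional[np.ndarray]
) -> np.ndarray:
    """Pixels adjacent to the ROI edge or on the image border."""
    zone = np.zeros(shape, dtype=bool)
    zone[0, :] = zone[-1, :] = True
    zone[:, 0] = zone[:, -1] = True
    if roi is not None:
        from scipy.ndimage import binary_erosion

        ring = roi & ~binary_erosion(roi, iterations=1)
        zone |= ring
    return zone


def measure_plate(
    image: np.ndarray,
    mm_per_px: float,
    config: Optional[PipelineConfig] = None,
) -> list[PlaqueMeasurement]:
    """Full pipeline: subtract background, threshold inside the elliptical
    ROI, extract and filter particles."""
    config = config or PipelineConfig()
    flattened = subtract_background(image, config.rolling_ball_radius_px)
    roi = elliptical_roi_mask(image.shape, mm_per_px, config.roi_diameter_mm)
    mask = apply_threshold(
        flattened, config.threshold_lower, config.threshold_upper, roi
    )
    return analyze_particles(
        mask,
        mm_per_px,
        area_range_mm2=config.area_range_mm2,
        circularity_range=config.circularity_range,
        roi=roi,
    )


@dataclass(frozen=True)
class SampleSizeSummary:
    sample: str
    n: int
    mean_diameter_mm: float
    ci_low: float
    ci_high: float
    vs_reference_p: Optional[float] = None
    vs_reference_p_adjusted: Optional[float] = None
    significant: Optional[bool] = None


def plaque_size_report(
    measurements_by_sample: Mapping[str, Sequence[PlaqueMeasurement]],
    reference: Optional[str] = None,
    alpha: float = 0.05,
) -> list[SampleSizeSummary]:
    """Per-sample mean equivalent diameter with 95% CI; optional pairwise
    two-tailed t tests against a reference sample, Holm-corrected."""
    import warnings

    diameters = {}
    for sample, ms in measurements_by_sample.items():
        if len(ms) == 0:
            warnings.warn(f"sample {sample!r} has no plaques; skipped", stacklevel=2)
            continue
        diameters[sample] = [m.equivalent_diameter_mm for m in ms]

    raw_p: dict[str, float] = {}
    if reference is not None:
        if reference not in diameters:
            raise KeyError(f"reference sample {reference!r} missing or empty")
        for sample, d in diameters.items():
            if sample == reference:
                continue
            _, p = compare_groups(d, diameters[reference], tails="two")
            raw_p[sample] = p
    holm = holm_bonferroni(list(raw_p.values()), alpha=alpha) if raw_p else None

    out = []
    for sample, d in diameters.items():
        if len(d) >= 2:
            est = summarize_replicates(d)
            ci_low, ci_high = est.ci
        else:
            ci_low = ci_high = d[0]
        p = raw_p.get(sample)
        idx = list(raw_p).index(sample) if sample in raw_p else None
        out.append(
            SampleSizeSummary(
                sample=sample,
                n=len(d),
                mean_diameter_mm=float(np.mean(d)),
                ci_low=ci_low,
                ci_high=ci_high,
                vs_reference_p=p,
                vs_reference_p_adjusted=holm.adjusted[idx] if idx is not None else None,
                significant=holm.rejected[idx] if idx is not None else None,
            )
        )
    return out


def measurements_frame(measurements: Sequence[PlaqueMeasurement]) -> pd.DataFrame:
    """Per-plaque table (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "area_mm2": m.area_mm2,
                "equivalent_diameter_mm": m.equivalent_diameter_mm,
                "perimeter_mm": m.perimeter_mm,
                "circularity": m.circularity,
                "x_mm": m.centroid_mm[0],
                "y_mm": m.centroid_mm[1],
            }
            for m in measurements
        ]
    )
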