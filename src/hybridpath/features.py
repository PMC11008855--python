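"""Morphometric feature extraction: 33 features per image/mask pair.

The vector is the concatenation, in fixed order, of three families describing
segmented nuclei: 11 geometric descriptors (sizes, perimeters, shape ratios,
fragment counts), 8 directional radial extents (centroid-to-boundary distance
along the eight compass directions, capturing shape irregularity), and 14
intensity statistics over the object pixels.  Geometric and directional
features see only the mask; intensity features see the grayscale image under
the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skimage import measure

GEOMETRIC_NAMES = [
    "geo_total_area",
    "geo_mean_area",
    "geo_total_perimeter",
    "geo_mean_roundness",
    "geo_fragment_count",
    "geo_mean_eccentricity",
    "geo_mean_solidity",
    "geo_mean_extent",
    "geo_mean_equiv_diameter",
    "geo_area_sd",
    "geo_perimeter_sd",
]
DIRECTIONAL_NAMES = [
    "dir_extent_N", "dir_extent_NE", "dir_extent_E", "dir_extent_SE",
    "dir_extent_S", "dir_extent_SW", "dir_extent_W", "dir_extent_NW",
]
INTENSITY_NAMES = [
    "int_mean", "int_sd", "int_range", "int_min", "int_max", "int_median",
    "int_p25", "int_p75", "int_skewness", "int_kurtosis", "int_entropy",
    "int_mean_gradient", "int_contrast", "int_cv",
]

FEATURE_NAMES = GEOMETRIC_NAMES + DIRECTIONAL_NAMES + INTENSITY_NAMES
FAMILY_SLICES = {
    "geometric": slice(0, 11),
    "directional": slice(11, 19),
    "intensity": slice(19, 33),
}

# unit steps (drow, dcol) for N, NE, E, SE, S, SW, W, NW in image coordinates
_DIRECTIONS = np.array([
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)
], dtype=np.float64)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)

#: components smaller than this are skipped when averaging directional extents
MIN_COMPONENT_AREA = 10


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = tuple(FEATURE_NAMES)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (33,):
            raise ValueError(f"feature vector must have length 33, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    m = (m > 0).astype(np.uint8)
    if m.sum() == 0:
        raise ValueError("mask has no object pixels")
    return m


def geometric_features(mask: np.ndarray) -> np.ndarray:
    """11 geometric descriptors, region-aggregated over 8-connected components."""
    m = _check_mask(mask)
    labels = measure.label(m, connectivity=2)
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props], dtype=np.float64)
    perims = np.array([p.perimeter for p in props], dtype=np.float64)
    # single-pixel components have zero perimeter; treat them as round points
    roundness = np.where(perims > 0, 4 * np.pi * areas / np.maximum(perims, 1e-12) ** 2, 1.0)
    return np.array([
        areas.sum(),
        areas.mean(),
        perims.sum(),
        roundness.mean(),
        float(len(props)),
        float(np.mean([p.eccentricity for p in props])),
        float(np.mean([p.solidity for p in props])),
        float(np.mean([p.extent for p in props])),
        float(np.mean([p.equivalent_diameter_area for p in props])),
        areas.std(),
        perims.std(),
    ])


def _radial_extent(component: np.ndarray, centroid: tuple[float, float]) -> np.ndarray:
    """March from the centroid along each compass direction until leaving the
    component; returns the 8 distances in pixels."""
    h, w = component.shape
    r0, c0 = centroid
    out = np.empty(8)
    for k, (dr, dc) in enumerate(_DIRECTIONS):
        t, last_inside = 0.0, 0.0
        while True:
            r = r0 + t * dr
            c = c0 + t * dc
            ri, ci = int(round(r)), int(round(c))
            if ri < 0 or ri >= h or ci < 0 or ci >= w or not component[ri, ci]:
                break
            last_inside = t
            t += 0.25
        out[k] = last_inside
    return out


def directional_features(mask: np.ndarray) -> np.ndarray:
    """Mean radial extent along N, NE, E, SE, S, SW, W, NW over components.

    Components below ``MIN_COMPONENT_AREA`` pixels are excluded from the
    average unless no component qualifies, in which case all are used.
    """
    m = _check_mask(mask)
    labels = measure.label(m, connectivity=2)
    props = measure.regionprops(labels)
    big = [p for p in props if p.area >= MIN_COMPONENT_AREA] or props
    extents = np.zeros((len(big), 8))
    for i, p in enumerate(big):
        comp = labels == p.label
        extents[i] = _radial_extent(comp, p.centroid)
    return extents.mean(axis=0)


def intensity_features(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """14 intensity statistics over object pixels (image under the mask)."""
    m = _check_mask(mask)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        from hybridpath.fixtures import to_luminance
        img = to_luminance(image).astype(np.float64)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    vals = img[m > 0]
    mean = vals.mean()
    sd = vals.std()
    if sd > 0:
        skew = float(sps.skew(vals))
        kurt = float(sps.kurtosis(vals))  # excess kurtosis
    else:
        skew, kurt = 0.0, 0.0
    hist, _ = np.histogram(vals, bins=256, range=(0, 256))
    p = hist[hist > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())
    gr, gc = np.gradient(img)
    grad_mag = np.hypot(gr, gc)[m > 0].mean()
    bg = img[m == 0]
    contrast = mean - bg.mean() if bg.size else 0.0
    cv = sd / mean if mean != 0 else 0.0
    return np.array([
        mean, sd, vals.max() - vals.min(), vals.min(), vals.max(),
        float(np.median(vals)), float(np.percentile(vals, 25)),
        float(np.percentile(vals, 75)), skew, kurt, entropy,
        grad_mag, contrast, cv,
    ])


def extract_features(image: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """Full 33-feature vector: [geometric(11) | directional(8) | intensity(14)]."""
    values = np.concatenate([
        geometric_features(mask),
        directional_features(mask),
        intensity_features(image, mask),
    ])
    return FeatureVector(values=values)
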