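"""Synthetic fixtures and standard-format I/O.

Images are plain 2-D (grayscale) or H×W×3 (RGB) uint8 numpy arrays with
intensities in [0, 255]; coordinates are row-major, 0-based, origin top-left.
The generators here stand in for real histopathology tiles: salt-and-pepper
corrupted pairs for the denoiser, bimodal "tissue" phantoms with known nuclei
masks for segmentation and feature extraction, and 33-column feature tables
with a known informative subset for the feature-selection and classifier
stages.  Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from hybridpath.features import FEATURE_NAMES

N_FEATURES = 33

#: Rec. 601 luma weights used whenever an RGB tile must be reduced to one channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def validate_image(image: np.ndarray) -> np.ndarray:
    """Check that ``image`` is a valid 8-bit raster and return it as uint8."""
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise ValueError(f"expected 2-D or H×W×3 image, got shape {arr.shape}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3×3, got {arr.shape[:2]}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    return arr.astype(np.uint8)


def to_luminance(image: np.ndarray) -> np.ndarray:
    """RGB → rounded 8-bit luminance; grayscale passes through."""
    arr = validate_image(image)
    if arr.ndim == 2:
        return arr
    w = np.asarray(LUMA_WEIGHTS)
    return np.clip(np.round(arr.astype(np.float64) @ w), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Salt-and-pepper corruption model.

    ``density`` is the fraction of pixels corrupted; of those, ``salt_fraction``
    are driven to 255 (salt) and the rest to 0 (pepper).
    """

    density: float
    salt_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must be in [0, 1], got {self.density}")
        if not 0.0 <= self.salt_fraction <= 1.0:
            raise ValueError(f"salt_fraction must be in [0, 1], got {self.salt_fraction}")


@dataclass(frozen=True)
class PhantomSpec:
    """Bimodal tissue phantom: bright elliptical nuclei on a dark textured background.

    Class-conditional morphology enters through the nucleus radius distribution
    (malignant nuclei are larger and more variable) and the intensity spread;
    the defaults give benign/malignant populations that are cleanly separable
    on mean nucleus area.  Intensities are kept within [1, 254] so that no
    clean pixel collides with the impulse-noise extremes.
    """

    size: tuple[int, int] = (128, 128)
    n_nuclei: int = 5
    class_label: str = "benign"
    radius_mean: float | None = None
    radius_sd: float | None = None
    eccentricity_range: tuple[float, float] | None = None
    intensity_mean: float = 190.0
    intensity_sd: float | None = None
    background_intensity: float = 60.0
    background_sd: float = 6.0
    seed: int = 0

    _CLASS_DEFAULTS = {
        "benign": {"radius_mean": 7.0, "radius_sd": 1.0,
                   "eccentricity_range": (0.75, 0.95), "intensity_sd": 8.0},
        "malignant": {"radius_mean": 10.0, "radius_sd": 2.0,
                      "eccentricity_range": (0.45, 0.9), "intensity_sd": 16.0},
    }

    def __post_init__(self) -> None:
        if self.class_label not in self._CLASS_DEFAULTS:
            raise ValueError(f"class_label must be benign|malignant, got {self.class_label!r}")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.size[0] < 3 or self.size[1] < 3:
            raise ValueError("phantom must be at least 3×3")
        d = self._CLASS_DEFAULTS[self.class_label]
        for name in ("radius_mean", "radius_sd", "eccentricity_range", "intensity_sd"):
            if getattr(self, name) is None:
                object.__setattr__(self, name, d[name])


@dataclass(frozen=True)
class FeatureDatasetSpec:
    """Synthetic 33-column feature table with a known informative subset.

    Informative columns carry a class-conditional mean shift of
    ``effect_size`` (class 1 minus class 0); all other columns are
    class-independent Gaussian noise with standard deviation ``noise_sd``.
    """

    n_samples: int = 200
    informative_indices: tuple[int, ...] = (0, 5, 12, 18, 25, 30)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    n_features: int = N_FEATURES

    def __post_init__(self) -> None:
        if self.n_features != N_FEATURES:
            raise ValueError(f"n_features is fixed at {N_FEATURES}")
        idx = tuple(self.informative_indices)
        if any(i < 0 or i >= N_FEATURES for i in idx):
            raise ValueError("informative_indices must lie in [0, 33)")
        if self.n_samples < 4:
            raise ValueError("need at least 2 samples per class")


def spec_to_yaml(spec, path: str | os.PathLike) -> None:
    """Serialize any of the spec dataclasses to a YAML file."""
    d = dataclasses.asdict(spec)
    d["__spec__"] = type(spec).__name__
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def spec_from_yaml(path: str | os.PathLike):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kind = d.pop("__spec__")
    cls = {"NoiseSpec": NoiseSpec, "PhantomSpec": PhantomSpec,
           "FeatureDatasetSpec": FeatureDatasetSpec}[kind]
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_saltpepper_pair(clean: np.ndarray, spec: NoiseSpec) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt ``clean`` with salt-and-pepper noise; return (clean, noisy).

    Each pixel is independently corrupted with probability ``spec.density``
    (per channel for RGB inputs); corrupted pixels take the value 255 with
    probability ``spec.salt_fraction`` and 0 otherwise.  Uncorrupted pixels
    are returned bit-identical.
    """
    clean = validate_image(clean)
    rng = np.random.default_rng(spec.seed)
    hit = rng.random(clean.shape) < spec.density
    salt = rng.random(clean.shape) < spec.salt_fraction
    noisy = clean.copy()
    noisy[hit & salt] = 255
    noisy[hit & ~salt] = 0
    return clean, noisy


def _draw_ellipse(img: np.ndarray, mask: np.ndarray, label_map: np.ndarray,
                  label: int, center: tuple[float, float], a: float, b: float,
                  theta: float, intensity: float) -> None:
    """Paint one anti-aliased ellipse and its exact binary footprint."""
    h, w = img.shape
    r0, c0 = center
    ext = int(np.ceil(max(a, b))) + 2
    rlo, rhi = max(0, int(r0) - ext), min(h, int(r0) + ext + 1)
    clo, chi = max(0, int(c0) - ext), min(w, int(c0) + ext + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    # normalized radial coordinate: 1 on the ellipse boundary
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    inside = rho <= 1.0
    # ~1-px anti-aliasing skirt keeps edges smooth without growing the mask
    cover = np.clip((1.0 - rho) * min(a, b) + 0.5, 0.0, 1.0)
    patch = img[rlo:rhi, clo:chi]
    patch[:] = (1 - cover) * patch + cover * intensity
    mask[rlo:rhi, clo:chi][inside] = 1
    label_map[rlo:rhi, clo:chi][inside] = label


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, str]:
    """Generate a phantom tile; return (image, true nuclei mask, class label).

    Nuclei are placed by rejection sampling so that their footprints never
    touch, making the mask's connected-component count exactly ``n_nuclei``.
    Raises ``RuntimeError`` when the requested nuclei cannot be placed.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    img = np.clip(
        rng.normal(spec.background_intensity, spec.background_sd, (h, w)), 1, 254
    )
    mask = np.zeros((h, w), dtype=np.uint8)
    label_map = np.zeros((h, w), dtype=np.int32)

    placed: list[tuple[float, float, float]] = []  # (r, c, major axis)
    for k in range(spec.n_nuclei):
        radius = max(1.5, rng.normal(spec.radius_mean, spec.radius_sd))
        q = rng.uniform(*spec.eccentricity_range)  # minor/major axis ratio
        a = radius / np.sqrt(q)
        b = radius * np.sqrt(q)
        theta = rng.uniform(0, np.pi)
        ok = False
        for _ in range(500):
            r0 = rng.uniform(a + 1, h - a - 2) if h > 2 * a + 4 else None
            c0 = rng.uniform(a + 1, w - a - 2) if w > 2 * a + 4 else None
            if r0 is None or c0 is None:
                break
            if all(np.hypot(r0 - pr, c0 - pc) > a + pa + 3 for pr, pc, pa in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place nucleus {k + 1}/{spec.n_nuclei} in a "
                f"{h}×{w} phantom (radius {radius:.1f})"
            )
        intensity = np.clip(rng.normal(spec.intensity_mean, spec.intensity_sd), 1, 254)
        _draw_ellipse(img, mask, label_map, k + 1, (r0, c0), a, b, theta, intensity)
        placed.append((r0, c0, a))

    img = np.clip(np.round(img), 1, 254).astype(np.uint8)
    return img, mask, spec.class_label


def make_feature_dataset(spec: FeatureDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a (n × 33) feature matrix and balanced binary labels."""
    n = spec.n_samples
    if n // 2 < 2 or n - n // 2 < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(spec.seed)
    y = np.zeros(n, dtype=np.int64)
    y[n // 2:] = 1
    X = rng.normal(0.0, spec.noise_sd, (n, N_FEATURES))
    for j in spec.informative_indices:
        X[y == 1, j] += spec.effect_size
    perm = rng.permutation(n)
    return X[perm], y[perm]


def augment(images: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Expand a batch three-fold: originals, 90° rotations, horizontal mirrors."""
    if len(images) == 0:
        raise ValueError("augment requires a non-empty list of images")
    imgs = [validate_image(im) for im in images]
    rotated = [np.rot90(im) for im in imgs]
    mirrored = [np.fliplr(im) for im in imgs]
    return imgs + rotated + mirrored


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_image(path: str | os.PathLike) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return validate_image(arr)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    image = validate_image(image)
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    iio.imwrite(path, image)


def read_features(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    """Read a feature CSV; returns (matrix, column names)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    return df.to_numpy(dtype=np.float64), list(df.columns)


def write_features(matrix: np.ndarray, path: str | os.PathLike,
                   names: Sequence[str] | None = None) -> None:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if names is None:
        names = FEATURE_NAMES if matrix.shape[1] == N_FEATURES else [
            f"f{i}" for i in range(matrix.shape[1])
        ]
    pd.DataFrame(matrix, columns=list(names)).to_csv(path, index=False, float_format="%.12g")
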