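"""Adaptive switching modified decision-based unsymmetrical trimmed median filter.

Salt-and-pepper (impulse) noise drives pixels to the extremes 0 or 255; the
detector flags exactly those values.  Flagged pixels are restored in raster
order by a case analysis on how many non-noisy pixels (NNPs) surround them:

* Case A — every 3×3 neighbor is noisy: the window expands to 5×5, 7×7, then
  9×9; the first window containing any NNP contributes the median of its
  NNPs.  If even the 9×9 window is fully noisy, the global median of the
  pixels restored so far is used (127 if none yet).
* Case B — 3 to 8 NNPs in the 3×3 window: the trimmed median (median of the
  NNPs alone) replaces the pixel.
* Case C — only 1 or 2 NNPs in the 3×3 window: the two smallest sorted NNPs
  become α and β, and a 5×5 window is consulted: more than 3 NNPs there →
  their mean; exactly 3 → their median; exactly 2 → (α+β)/2; a single NNP →
  α itself.

Restored values are clamped to [1, 254] so the detector never re-flags them,
and later windows see earlier restorations (decision-based family
convention).  Boundaries are handled by symmetric reflection.  Note the
detector cannot distinguish true 0/255 image content from noise; such pixels
are treated as noisy (a documented false-positive of the value-based
detector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

VALID_WINDOW_SIZES = (3, 5, 7, 9)


def detect_noise(image: np.ndarray) -> np.ndarray:
    """Binary mask: 1 where the pixel is an impulse extreme (0 or 255)."""
    from hybridpath.fixtures import validate_image

    img = validate_image(image)
    return ((img == 0) | (img == 255)).astype(np.uint8)


@njit(cache=True)
def _reflect(i: int, n: int) -> int:
    while i < 0 or i >= n:
        if i < 0:
            i = -i - 1
        else:
            i = 2 * n - i - 1
    return i


@njit(cache=True)
def _window_nnp(img, mask, i, j, s, include_center):
    """Collect the non-noisy values of the s×s window centered at (i, j)."""
    h, w = img.shape
    half = s // 2
    out = np.empty(s * s, dtype=np.float64)
    k = 0
    for di in range(-half, half + 1):
        for dj in range(-half, half + 1):
            if not include_center and di == 0 and dj == 0:
                continue
            r = _reflect(i + di, h)
            c = _reflect(j + dj, w)
            if mask[r, c] == 0:
                out[k] = img[r, c]
                k += 1
    return out[:k]


@njit(cache=True)
def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@njit(cache=True)
def _clamp(v: int) -> int:
    if v < 1:
        return 1
    if v > 254:
        return 254
    return v


@njit(cache=True)
def _restore_one(img, mask, i, j):
    """Restore one flagged pixel; returns -1 when even the 9×9 window is all noise."""
    nnp3 = _window_nnp(img, mask, i, j, 3, False)
    c3 = nnp3.size
    if c3 == 0:
        # Case A: expand until any NNP appears
        for s in (5, 7, 9):
            vals = _window_nnp(img, mask, i, j, s, False)
            if vals.size > 0:
                return _clamp(_round_half_up(np.median(vals)))
        return -1
    if c3 >= 3:
        # Case B: trimmed median over the 3×3 NNPs
        return _clamp(_round_half_up(np.median(nnp3)))
    # Case C: 1 or 2 NNPs in the 3×3 window
    srt = np.sort(nnp3)
    alpha = srt[0]
    beta = srt[1] if c3 > 1 else -1.0
    nnp5 = _window_nnp(img, mask, i, j, 5, False)
    c5 = nnp5.size
    if c5 > 3:
        return _clamp(_round_half_up(nnp5.mean()))
    if c5 == 3:
        return _clamp(_round_half_up(np.median(nnp5)))
    if c5 == 2:
        if beta < 0.0:
            beta = np.sort(nnp5)[1]
        return _clamp(_round_half_up((alpha + beta) / 2.0))
    return _clamp(_round_half_up(alpha))


@njit(cache=True)
def _asmdbutmf_core(img, mask):
    """Raster-order restoration; ``img`` and ``mask`` are modified in place."""
    h, w = img.shape
    restored = np.empty(h * w, dtype=np.float64)
    n_restored = 0
    # first pass: pixels that cannot be restored yet (all-noise out to 9×9)
    # fall back to the running median of restorations, or 127
    for i in range(h):
        for j in range(w):
            if mask[i, j] == 1:
                v = _restore_one(img, mask, i, j)
                if v < 0:
                    if n_restored > 0:
                        v = _clamp(_round_half_up(np.median(restored[:n_restored])))
                    else:
                        v = 127
                img[i, j] = v
                mask[i, j] = 0
                restored[n_restored] = v
                n_restored += 1
    return img


@dataclass(frozen=True)
class WindowView:
    """The s×s neighborhood of a pixel with its noise bookkeeping."""

    center: tuple[int, int]
    size: int
    values: np.ndarray
    noise_flags: np.ndarray
    c_np: int
    c_nnp: int
    alpha: float | None
    beta: float | None


def extract_window(image: np.ndarray, mask: np.ndarray, i: int, j: int,
                   s: int) -> WindowView:
    """Gather the s×s window at (i, j) with reflection padding.

    Counts include the center pixel; ``alpha``/``beta`` are the first and
    second elements of the sorted non-noisy values (None when undefined).
    """
    if s not in VALID_WINDOW_SIZES:
        raise ValueError(f"window size must be one of {VALID_WINDOW_SIZES}, got {s}")
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask, dtype=np.uint8)
    h, w = img.shape
    half = s // 2
    rows = [_py_reflect(i + d, h) for d in range(-half, half + 1)]
    cols = [_py_reflect(j + d, w) for d in range(-half, half + 1)]
    vals = img[np.ix_(rows, cols)]
    flags = msk[np.ix_(rows, cols)]
    nnp = np.sort(vals[flags == 0])
    return WindowView(
        center=(i, j), size=s, values=vals, noise_flags=flags,
        c_np=int((flags == 1).sum()), c_nnp=int(nnp.size),
        alpha=float(nnp[0]) if nnp.size >= 1 else None,
        beta=float(nnp[1]) if nnp.size >= 2 else None,
    )


def _py_reflect(i: int, n: int) -> int:
    while i < 0 or i >= n:
        i = -i - 1 if i < 0 else 2 * n - i - 1
    return i


def restore_pixel(image: np.ndarray, mask: np.ndarray, i: int, j: int) -> int:
    """Restore the flagged pixel (i, j) by the case logic; pure reference path.

    Returns the replacement intensity in [1, 254]; raises ``ValueError`` if
    the pixel is not flagged, or ``RuntimeError`` when all windows out to 9×9
    contain only noise (the full-image filter handles that via its fallback).
    """
    msk = np.asarray(mask, dtype=np.uint8)
    if msk[i, j] != 1:
        raise ValueError(f"pixel ({i}, {j}) is not flagged noisy")
    img = np.asarray(image, dtype=np.float64)
    v = _restore_one(img, msk, i, j)
    if v < 0:
        raise RuntimeError(f"no non-noisy pixel within the 9×9 window of ({i}, {j})")
    return int(v)


def asmdbutmf(image: np.ndarray) -> np.ndarray:
    """Filter an 8-bit image; RGB inputs are processed per channel.

    Non-noisy pixels pass through unchanged; clean images are returned
    bit-identical.
    """
    from hybridpath.fixtures import validate_image

    img = validate_image(image)
    if img.ndim == 3:
        out = np.stack([asmdbutmf(img[:, :, c]) for c in range(3)], axis=2)
        return out
    mask = ((img == 0) | (img == 255)).astype(np.uint8)
    if mask.sum() == 0:
        return img.copy()
    work = img.astype(np.float64)
    _asmdbutmf_core(work, mask)
    return np.clip(np.round(work), 0, 255).astype(np.uint8)
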