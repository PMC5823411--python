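"""Image and mask I/O plus per-pixel features.

All in-memory images are float64 RGB arrays with values in [0, 1]; 8-bit
integers exist only at file boundaries.  Coordinates are row-major and
0-based; rectangles are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

#: Rec. 601 luma weights used to collapse RGB to a single channel.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _as_float01(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer or float image array to float64 in [0, 1]."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    out = arr.astype(np.float64)
    if out.size and out.max() > 1.0:  # e.g. float images on a 0-255 scale
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as an ``(H, W, 3)`` float RGB array in [0, 1].

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped; 8-/16-bit integer data are rescaled to [0, 1].

    Raises
    ------
    IOError
        If the file cannot be read or decoded.
    ValueError
        If the decoded image has zero area.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface decoder errors uniformly
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"unsupported image layout {arr.shape} in {path!r}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError(f"zero-area image in {path!r}")
    return _as_float01(arr)


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask PNG (any nonzero/over-half value is foreground)."""
    arr = load_image(path)
    return (arr.mean(axis=-1) > 0.5).astype(np.uint8)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit PNG with foreground = 255."""
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    iio.imwrite(path, out)


def save_saliency(path: str | os.PathLike, saliency: np.ndarray) -> None:
    """Write a [0,1] saliency map as an 8-bit grayscale PNG (linear 0-255)."""
    out = np.clip(np.asarray(saliency, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, np.rint(out * 255).astype(np.uint8))


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check the working-representation invariants of an RGB image."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image too small: {img.shape[:2]} (minimum 8x8)")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


def downsample(img: np.ndarray, target_side: int = 64) -> np.ndarray:
    """Resize an RGB image to a square ``target_side`` working frame.

    Uses anti-aliased interpolation; aspect ratio is deliberately not
    preserved because all downstream learning is per-pixel.
    """
    img = validate_rgb(img)
    if target_side < 8:
        raise ValueError(f"target_side must be >= 8, got {target_side}")
    if img.shape[0] == target_side and img.shape[1] == target_side:
        return img.copy()
    out = resize(
        img,
        (target_side, target_side, 3),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


def luminance(img: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance ``0.299 R + 0.587 G + 0.114 B`` in [0, 1]."""
    img = validate_rgb(img)
    w = np.asarray(LUMA_WEIGHTS)
    return img @ w


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean norm of central-difference gradients.

    Gradients are taken per channel with the border handled by edge
    replication, then combined as ``sqrt(sum_c dr_c^2 + dc_c^2)``.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[..., None]
    padded = np.pad(arr, ((1, 1), (1, 1), (0, 0)), mode="edge")
    dr = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    dc = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    return np.sqrt((dr**2 + dc**2).sum(axis=-1))


def resize_mask_to(mask: np.ndarray, height: int, width: int) -> np.ndarray:
    """Nearest-neighbour rescaling of a {0,1} mask to ``height x width``."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    if mask.shape == (height, width):
        return (mask > 0).astype(np.uint8)
    out = resize(
        (mask > 0).astype(np.float64),
        (height, width),
        order=0,
        anti_aliasing=False,
        preserve_range=True,
    )
    return (out > 0.5).astype(np.uint8)


def minmax01(field: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalize a field to [0, 1].

    Returns ``(normalized, degenerate)`` where a constant input maps to all
    zeros with the degenerate flag set.  "Constant" includes ranges at
    floating-point round-off scale, which carry no signal and must not be
    stretched to full range.
    """
    field = np.asarray(field, dtype=np.float64)
    lo = field.min()
    hi = field.max()
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        return np.zeros_like(field), True
    return (field - lo) / (hi - lo), False
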