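"""Fixation regions and pixel-sample drawing.

A fixation region is either the minimal rectangle around the top-n saliency
pixels (the initial "gaze box") or an arbitrary binary mask (the refined
fixation area in later feedback iterations).  Positive training pixels are
drawn from high-gradient locations inside the region - edges and textured
nucleus pixels carry the object's colour signature - while negatives come
uniformly from everywhere outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epelm import SampleSet


@dataclass
class FixationRegion:
    """Where positive samples come from: a box or a mask.

    ``box`` is a half-open rectangle ``(r0, r1, c0, c1)``; ``fallback`` marks
    a region produced by the degenerate-saliency fallback rule.
    """

    kind: str  # "box" | "mask"
    box: tuple[int, int, int, int] | None = None
    mask: np.ndarray | None = None
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.kind == "box":
            if self.box is None:
                raise ValueError("box region requires box coordinates")
            r0, r1, c0, c1 = self.box
            if r1 <= r0 or c1 <= c0:
                raise ValueError(f"box {self.box} has non-positive area")
        elif self.kind == "mask":
            if self.mask is None:
                raise ValueError("mask region requires a mask")
            self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)
            if self.mask.sum() == 0:
                raise ValueError("mask region has no foreground pixel")
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the region as a boolean array of the given image shape."""
        if self.kind == "mask":
            if self.mask.shape != tuple(shape):
                raise ValueError(
                    f"region mask shape {self.mask.shape} does not match {shape}"
                )
            return self.mask.astype(bool)
        r0, r1, c0, c1 = self.box
        if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
            raise ValueError(f"box {self.box} exceeds image bounds {shape}")
        out = np.zeros(shape, dtype=bool)
        out[r0:r1, c0:c1] = True
        return out


def top_n_box(saliency: np.ndarray, n: int = 100) -> FixationRegion:
    """Minimal axis-aligned rectangle around the n most salient pixels.

    Ties at the cutoff value are broken by row-major scan order so that
    exactly n pixels are used.  A constant saliency map falls back to a
    centred rectangle of half the image side, flagged in the result.
    """
    saliency = np.asarray(saliency, dtype=np.float64)
    if saliency.ndim != 2:
        raise ValueError("saliency map must be 2-D")
    h, w = saliency.shape
    if n < 1 or n > saliency.size:
        raise ValueError(f"n must be in [1, {saliency.size}], got {n}")
    if saliency.max() - saliency.min() <= 0.0:
        r0, c0 = h // 4, w // 4
        box = (r0, r0 + max(1, h // 2), c0, c0 + max(1, w // 2))
        return FixationRegion(kind="box", box=box, fallback=True)
    flat_order = np.argsort(-saliency.ravel(), kind="stable")[:n]
    rows, cols = np.unravel_index(flat_order, saliency.shape)
    box = (int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)
    return FixationRegion(kind="box", box=box)


def sample_positives(
    img: np.ndarray,
    region: FixationRegion,
    grad: np.ndarray,
    m: int = 500,
    seed: int = 0,
) -> SampleSet:
    """Draw m positive pixels (target +1) from the high-gradient part of the
    fixation region.

    "High gradient" means gradient magnitude at or above the within-region
    median, which keeps the candidate pool size stable across images.  If the
    pool holds fewer than m pixels, sampling is with replacement.
    """
    img = np.asarray(img, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    shape = img.shape[:2]
    if grad.shape != shape:
        raise ValueError("gradient field shape does not match image")
    inside = region.to_mask(shape)
    if not inside.any():
        raise ValueError("fixation region is empty")
    median = np.median(grad[inside])
    pool = np.argwhere(inside & (grad >= median))
    if len(pool) == 0:  # cannot happen with >=-median rule, kept as guard
        pool = np.argwhere(inside)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=m, replace=len(pool) < m)
    coords = pool[idx]
    feats = img[coords[:, 0], coords[:, 1]]
    return SampleSet(features=feats, targets=np.ones(m), coords=coords)


def sample_negatives(
    img: np.ndarray,
    region: FixationRegion,
    m: int = 500,
    seed: int = 0,
) -> SampleSet:
    """Draw m negative pixels (target -1) uniformly from outside the region.

    No gradient filter applies to negatives.  Raises if the region covers the
    whole image (the feedback loop treats that as divergence upstream).
    """
    img = np.asarray(img, dtype=np.float64)
    shape = img.shape[:2]
    outside = ~region.to_mask(shape)
    pool = np.argwhere(outside)
    if len(pool) == 0:
        raise ValueError("fixation region covers the whole image; no negatives")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=m, replace=len(pool) < m)
    coords = pool[idx]
    feats = img[coords[:, 0], coords[:, 1]]
    return SampleSet(features=feats, targets=-np.ones(m), coords=coords)


def merge(pos: SampleSet, neg: SampleSet) -> SampleSet:
    """Concatenate positive and negative halves (positives first)."""
    if pos.dim != neg.dim:
        raise ValueError("sample halves have different feature dimensions")
    coords = None
    if pos.coords is not None and neg.coords is not None:
        coords = np.vstack([pos.coords, neg.coords])
    return SampleSet(
        features=np.vstack([pos.features, neg.features]),
        targets=np.concatenate([pos.targets, neg.targets]),
        coords=coords,
    )
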