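"""Seeded synthetic fixtures with exact ground truth.

Two scene families:

* blood-smear-like micrographs: a bright background carrying faint
  erythrocyte (RBC) discs, one or more darkly stained nucleated cells
  (dark irregular nucleus inside intermediate cytoplasm), plus an
  illumination gradient, a global colour cast and Gaussian noise - the
  kinds of variability different smear preparations introduce;
* two-object natural-image-like scenes: a textured background with two
  colour-distinct compact objects.

Ground truth is the union of whole nucleated cells (nucleus + cytoplasm);
RBC discs are never foreground.  Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import LUMA_WEIGHTS, save_mask


def _lum(color) -> float:
    return float(np.dot(np.asarray(color), LUMA_WEIGHTS))


@dataclass
class SmearParams:
    """Scene description for one synthetic smear image.

    ``cell_radius_mean``/``sd`` are in pixels at ``image_side`` resolution;
    ``nucleus_fraction`` is the nucleus radius as a fraction of the cell
    radius.  Colours are RGB in [0, 1] and must keep the staining order
    nucleus < cytoplasm < background in mean luminance.
    """

    image_side: int = 128
    n_cells: int = 1
    cell_radius_mean: float = 20.0
    cell_radius_sd: float = 3.0
    nucleus_fraction: float = 0.55
    background_color: tuple[float, float, float] = (0.92, 0.90, 0.88)
    rbc_color: tuple[float, float, float] = (0.86, 0.74, 0.70)
    cytoplasm_color: tuple[float, float, float] = (0.65, 0.62, 0.80)
    nucleus_color: tuple[float, float, float] = (0.35, 0.20, 0.50)
    n_rbc: int = 12
    illumination_slope: float = 0.05
    color_cast: tuple[float, float, float] = (0.02, 0.0, -0.02)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_color", "rbc_color", "cytoplasm_color", "nucleus_color"):
            col = np.asarray(getattr(self, name), dtype=float)
            if col.min() < 0 or col.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not _lum(self.nucleus_color) < _lum(self.cytoplasm_color) < _lum(self.background_color):
            raise ValueError(
                "staining order violated: need luminance(nucleus) < "
                "luminance(cytoplasm) < luminance(background)"
            )
        if not 0.0 < self.nucleus_fraction <= 1.0:
            raise ValueError("nucleus_fraction must be in (0, 1]")


def _blend(img: np.ndarray, alpha: np.ndarray, color) -> None:
    """In-place alpha blend of a flat colour into the canvas."""
    a = alpha[..., None]
    img *= 1.0 - a
    img += a * np.asarray(color)


def _ellipse_alpha(rr, cc, center, axes, angle, edge: float = 1.5) -> np.ndarray:
    """Soft-edged rotated-ellipse coverage in [0, 1]."""
    dy = rr - center[0]
    dx = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / axes[1]
    v = (-sa * dx + ca * dy) / axes[0]
    # Approximate signed distance (in px) from the unit-ellipse boundary.
    q = np.sqrt(u**2 + v**2)
    dist = (1.0 - q) * min(axes)
    return np.clip(dist / edge + 0.5, 0.0, 1.0)


def _blob_alpha(rr, cc, center, radius, wobble, rng, edge: float = 1.5) -> np.ndarray:
    """Irregular blob: an ellipse whose radius is modulated in angle."""
    dy = rr - center[0]
    dx = cc - center[1]
    theta = np.arctan2(dy, dx)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    r_local = radius * (
        1.0 + wobble * np.sin(3 * theta + phase1) + 0.5 * wobble * np.sin(5 * theta + phase2)
    )
    dist = r_local - np.sqrt(dx**2 + dy**2)
    return np.clip(dist / edge + 0.5, 0.0, 1.0)


def generate_smear(params: SmearParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a smear scene.

    Returns ``(image, truth, nucleus_truth)`` where ``truth`` is the union of
    whole nucleated cells and ``nucleus_truth`` only their nuclei.

    Raises
    ------
    ValueError
        If the requested cells cannot fit into the frame.
    """
    side = params.image_side
    rng = np.random.default_rng(params.seed)
    max_radius = params.cell_radius_mean * 1.5
    if params.n_cells > 0 and 2 * max_radius + 4 > side:
        raise ValueError(
            f"cells of radius ~{params.cell_radius_mean} do not fit a "
            f"{side}x{side} frame"
        )
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    img = np.ones((side, side, 3)) * np.asarray(params.background_color)

    # Illumination gradient: smooth multiplicative drift across the frame.
    drift = (rr + cc) / (2 * (side - 1)) - 0.5
    img *= (1.0 - 2.0 * params.illumination_slope * drift)[..., None]

    truth = np.zeros((side, side), dtype=bool)
    nucleus_truth = np.zeros((side, side), dtype=bool)

    # Stained nucleated cells first; RBCs must avoid them.
    centers: list[tuple[float, float]] = []
    for _ in range(params.n_cells):
        radius = float(
            np.clip(
                rng.normal(params.cell_radius_mean, params.cell_radius_sd),
                0.5 * params.cell_radius_mean,
                1.5 * params.cell_radius_mean,
            )
        )
        margin = radius * 1.3 + 2
        placed = False
        for _ in range(200):
            center = tuple(rng.uniform(margin, side - margin, size=2))
            if all(
                np.hypot(center[0] - c0, center[1] - c1) > 2.2 * radius
                for c0, c1 in centers
            ):
                placed = True
                break
        if not placed:
            raise ValueError("could not place all cells without overlap")
        centers.append(center)
        axes = (radius * rng.uniform(0.85, 1.15), radius * rng.uniform(0.85, 1.15))
        angle = rng.uniform(0, np.pi)
        cell_alpha = _ellipse_alpha(rr, cc, center, axes, angle)
        _blend(img, cell_alpha, params.cytoplasm_color)
        nuc_center = (
            center[0] + rng.uniform(-0.15, 0.15) * radius,
            center[1] + rng.uniform(-0.15, 0.15) * radius,
        )
        nuc_alpha = _blob_alpha(
            rr, cc, nuc_center, radius * params.nucleus_fraction, wobble=0.2, rng=rng
        )
        nuc_alpha = np.minimum(nuc_alpha, cell_alpha)
        _blend(img, nuc_alpha, params.nucleus_color)
        truth |= cell_alpha >= 0.5
        nucleus_truth |= nuc_alpha >= 0.5

    # Faint erythrocyte discs with central pallor, off the ground truth.
    rbc_radius = params.cell_radius_mean * 0.45
    for _ in range(params.n_rbc):
        for _ in range(50):
            center = tuple(rng.uniform(rbc_radius, side - rbc_radius, size=2))
            d = np.hypot(rr - center[0], cc - center[1])
            footprint = d <= rbc_radius + 2
            if not (footprint & truth).any():
                alpha = np.clip((rbc_radius - d) / 1.5 + 0.5, 0.0, 1.0)
                # ring profile: stronger rim, pale centre
                ring = 0.45 + 0.55 * np.clip(d / rbc_radius, 0.0, 1.0)
                _blend(img, alpha * ring, params.rbc_color)
                break

    img += np.asarray(params.color_cast)
    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return img, truth.astype(np.uint8), nucleus_truth.astype(np.uint8)


def generate_two_object_scene(
    seed: int = 0, side: int = 128
) -> tuple[np.ndarray, np.ndarray]:
    """Textured background plus two colour-distinct compact objects.

    The truth mask has exactly two connected components; both objects' mean
    colours sit far (>0.3 RGB distance) from the background tone.
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:side, 0:side].astype(np.float64)
    base = np.array([0.55, 0.58, 0.50])
    img = np.ones((side, side, 3)) * base
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(side, side)), sigma=6.0)
    img += 0.06 * texture[..., None]
    truth = np.zeros((side, side), dtype=bool)

    colors = (np.array([0.85, 0.15, 0.10]), np.array([0.10, 0.20, 0.85]))
    quarter = side // 4
    centers = (
        (rng.uniform(quarter, side - quarter), rng.uniform(quarter * 0.8, quarter * 1.6)),
        (rng.uniform(quarter, side - quarter), rng.uniform(side - quarter * 1.6, side - quarter * 0.8)),
    )
    for color, center in zip(colors, centers):
        radius = rng.uniform(0.10, 0.16) * side
        axes = (radius * rng.uniform(0.8, 1.2), radius * rng.uniform(0.8, 1.2))
        alpha = _ellipse_alpha(rr, cc, center, axes, rng.uniform(0, np.pi))
        _blend(img, alpha, color)
        truth |= alpha >= 0.5
    img += rng.normal(0.0, 0.015, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return img, truth.astype(np.uint8)


#: Preset scene conditions.  "easy" is the default smear; "hard" narrows the
#: RBC-to-background contrast gap and raises noise; "empty" has no stained
#: cell at all.
PRESETS = ("easy", "hard", "two-object", "empty")


def preset_params(preset: str, seed: int, rng: np.random.Generator) -> SmearParams:
    """Draw one image's parameters for a preset, jittered realistically."""
    if preset not in ("easy", "hard", "empty"):
        raise ValueError(f"unknown smear preset {preset!r}")
    jitter = rng.uniform(-0.03, 0.03, size=3)
    params = SmearParams(
        seed=seed,
        n_cells=0 if preset == "empty" else 1,
        cell_radius_mean=float(rng.uniform(17.0, 23.0)),
        n_rbc=int(rng.integers(8, 16)),
        illumination_slope=float(rng.uniform(0.02, 0.08)),
        color_cast=tuple(np.clip(jitter, -0.05, 0.05)),
        noise_sd=float(rng.uniform(0.015, 0.025)),
    )
    if preset == "hard":
        params = replace(
            params,
            rbc_color=(0.80, 0.66, 0.66),
            noise_sd=float(rng.uniform(0.03, 0.05)),
        )
    return params


def suite_params(n: int, base_seed: int = 0, preset: str = "easy") -> list[SmearParams]:
    """Parameter sets for an n-image suite, deterministic in ``base_seed``."""
    if n < 1:
        raise ValueError("suite size must be >= 1")
    rng = np.random.default_rng(base_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [preset_params(preset, int(s), rng) for s in seeds]


def generate_suite(
    n: int,
    base_seed: int,
    outdir: str | os.PathLike,
    preset: str = "easy",
) -> pd.DataFrame:
    """Write an n-image suite (images, truth masks, manifest CSV) to disk."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    os.makedirs(outdir, exist_ok=True)
    import imageio.v3 as iio

    rows = []
    if preset == "two-object":
        rng = np.random.default_rng(base_seed)
        seeds = rng.integers(0, 2**31 - 1, size=n)
        for i, seed in enumerate(seeds):
            img, truth = generate_two_object_scene(seed=int(seed))
            img_path = os.path.join(outdir, f"img_{i:03d}.png")
            mask_path = os.path.join(outdir, f"img_{i:03d}_truth.png")
            iio.imwrite(img_path, np.rint(img * 255).astype(np.uint8))
            save_mask(mask_path, truth)
            rows.append(
                {
                    "index": i,
                    "image": img_path,
                    "truth": mask_path,
                    "seed": int(seed),
                    "params": json.dumps({"preset": preset}),
                }
            )
    else:
        for i, params in enumerate(suite_params(n, base_seed, preset)):
            img, truth, _ = generate_smear(params)
            img_path = os.path.join(outdir, f"img_{i:03d}.png")
            mask_path = os.path.join(outdir, f"img_{i:03d}_truth.png")
            iio.imwrite(img_path, np.rint(img * 255).astype(np.uint8))
            save_mask(mask_path, truth)
            doc = {k: v for k, v in params.__dict__.items()}
            rows.append(
                {
                    "index": i,
                    "image": img_path,
                    "truth": mask_path,
                    "seed": params.seed,
                    "params": json.dumps(doc),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest
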