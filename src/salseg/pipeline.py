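"""The positive-feedback segmentation pipeline.

The method imitates fixational eye movements.  A fast fixation predictor
(spectral residual) proposes a coarse gaze box; pixels sampled inside and
outside that box train an EPELM on-line, whose binary per-member outputs
("stimuli") accumulate into a coarse saliency map; robust background
detection suppresses border-connected regions; then a sample-learn-classify
loop repeatedly re-fixates on the thresholded mask, adding fresh stimuli,
until two consecutive fixation masks are similar enough (F-measure >= 0.95)
- the perception has saturated - or an iteration cap is hit.

The accumulated stimulus mean is the saliency map; the final thresholded
fixation mask is the segmentation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml
from skimage.filters import threshold_otsu

from . import epelm, rbd, sampling
from .imaging import downsample, gradient_magnitude, luminance, resize_mask_to, validate_rgb
from .metrics import precision_recall
from .sr import spectral_residual
from skimage.transform import resize as _sk_resize

#: Offset between per-iteration RNG streams: each feedback "micro-scan"
#: is independent but reproducible.
ITER_SEED_STRIDE = 1000


@dataclass
class PipelineConfig:
    """All tunable knobs of the segmentation pipeline.

    Defaults follow the method's operating point: n=100 fixation pixels,
    m=500 samples per class, ensemble of p=3 PELMs with L=20 hidden nodes,
    about 100 superpixels, 64x64 working frame and a saturation threshold
    of F = 0.95.
    """

    n_fixation: int = 100
    m_samples: int = 500
    ensemble_p: int = 3
    hidden_l: int = 20
    superpixels_k: int = 100
    f_stop: float = 0.95
    max_iter: int = 20
    seed: int = 0
    work_side: int = 64
    threshold_method: str = "fixed"  # "fixed" | "otsu" | "mean_std"
    fixed_threshold: float = 0.5
    mean_std_k: float = 0.5
    beta2: float = 0.3
    sr_kernel: int = 3
    sr_sigma: float = 2.5
    sigma_clr: float = 10.0
    sigma_bndcon: float = 1.0
    mu: float = 0.1
    loop_region: str = "box"  # "box": re-derive a top-n box; "mask": sample from BW_i

    def __post_init__(self) -> None:
        if not 0.0 < self.f_stop <= 1.0:
            raise ValueError(f"f_stop must lie in (0, 1], got {self.f_stop}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.threshold_method not in ("otsu", "fixed", "mean_std"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.loop_region not in ("mask", "box"):
            raise ValueError(f"unknown loop_region {self.loop_region!r}")
        if not 5 <= self.hidden_l <= 30:
            warnings.warn(
                f"hidden_l={self.hidden_l} outside the usual 5-30 range",
                stacklevel=2,
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)


@dataclass
class PipelineState:
    """Mutable state threaded through the pipeline stages."""

    stimulus_sum: np.ndarray | None = None  # running sum of binary stimuli
    stimulus_count: int = 0
    saliency_current: np.ndarray | None = None
    coarse_saliency: np.ndarray | None = None  # snapshot after the coarse stage
    bw_prev: np.ndarray | None = None
    bw_curr: np.ndarray | None = None
    iteration: int = 0
    converged: bool = False
    degenerate: bool = False
    diverged: bool = False
    history: list[dict[str, Any]] = field(default_factory=list)


@dataclass
class SegmentResult:
    """Output of :func:`segment` at the original image geometry."""

    mask: np.ndarray
    saliency: np.ndarray
    report: dict[str, Any]
    state: PipelineState


def mask_similarity(a: np.ndarray, b: np.ndarray, beta2: float = 0.3) -> float:
    """F-measure similarity of mask ``a`` against reference mask ``b``.

    Two empty masks count as identical (similarity 1).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    res = precision_recall(a, b, beta2=beta2)
    if "both_empty" in res.flags:
        return 1.0
    return res.f_measure


def threshold_map(saliency: np.ndarray, method: str = "fixed",
                  fixed: float = 0.5, mean_std_k: float = 0.5) -> np.ndarray:
    """Binarize a saliency map; a constant map yields an empty mask.

    The default is a fixed cut at 0.5: the accumulated saliency map is a
    vote fraction, so 0.5 is the majority decision of the stimuli, matching
    the sign-threshold semantics of a single classification round.  Otsu
    and mean + k*std cuts are available for non-vote maps.
    """
    saliency = np.asarray(saliency, dtype=np.float64)
    if saliency.max() - saliency.min() <= 0.0:
        return np.zeros(saliency.shape, dtype=np.uint8)
    if method == "otsu":
        t = threshold_otsu(saliency)
    elif method == "fixed":
        t = fixed
    elif method == "mean_std":
        t = saliency.mean() + mean_std_k * saliency.std()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (saliency > t).astype(np.uint8)


def _learn_round(
    img64: np.ndarray,
    region: sampling.FixationRegion,
    cfg: PipelineConfig,
    grad: np.ndarray,
    base_seed: int,
) -> list[np.ndarray]:
    """One sample-learn-classify round; returns the p binary stimuli."""
    pos = sampling.sample_positives(
        img64, region, grad, m=cfg.m_samples, seed=base_seed + 1
    )
    neg = sampling.sample_negatives(img64, region, m=cfg.m_samples, seed=base_seed + 2)
    samples = sampling.merge(pos, neg)
    ensemble = epelm.train_ensemble(
        samples, p=cfg.ensemble_p, hidden_l=cfg.hidden_l, seed=base_seed + 3
    )
    stimuli, _ = epelm.classify_image(ensemble, img64)
    return stimuli


def _accumulate(state: PipelineState, stimuli: list[np.ndarray]) -> None:
    for stim in stimuli:
        if state.stimulus_sum is None:
            state.stimulus_sum = stim.astype(np.float64)
        else:
            state.stimulus_sum = state.stimulus_sum + stim
        state.stimulus_count += 1
    state.saliency_current = state.stimulus_sum / state.stimulus_count


def coarse_saliency(img64: np.ndarray, cfg: PipelineConfig) -> PipelineState:
    """Stage 1-2: SR fixation box, on-line EPELM, accumulated coarse map."""
    img64 = validate_rgb(img64)
    state = PipelineState()
    gray = luminance(img64)
    sr_map = spectral_residual(
        gray, avg_kernel_side=cfg.sr_kernel, smooth_sigma=cfg.sr_sigma
    )
    region = sampling.top_n_box(sr_map, n=cfg.n_fixation)
    grad = gradient_magnitude(img64)
    try:
        stimuli = _learn_round(img64, region, cfg, grad, base_seed=cfg.seed)
    except ValueError:
        # Fixation failed to localize (e.g. the box covers the whole frame
        # on featureless content): flag and return an empty result.
        state.degenerate = True
        state.stimulus_sum = np.zeros(img64.shape[:2])
        state.stimulus_count = 1
        state.saliency_current = state.stimulus_sum.copy()
        state.coarse_saliency = state.saliency_current.copy()
        state.bw_curr = np.zeros(img64.shape[:2], dtype=np.uint8)
        state.history.append(
            {
                "stage": "coarse",
                "fixation_box": list(region.box) if region.box else None,
                "fallback_box": region.fallback,
                "degenerate": True,
            }
        )
        return state
    _accumulate(state, stimuli)
    state.coarse_saliency = state.saliency_current.copy()
    state.history.append(
        {
            "stage": "coarse",
            "fixation_box": list(region.box) if region.box else None,
            "fallback_box": region.fallback,
            "stimulus_count": state.stimulus_count,
        }
    )
    return state


def suppress_background(
    state: PipelineState, img64: np.ndarray, cfg: PipelineConfig
) -> PipelineState:
    """Stage 3: RBD pass replacing the current map (accumulator retained)."""
    if state.saliency_current is None:
        raise ValueError("coarse stage must run before background suppression")
    if state.degenerate:
        return state
    optimized = rbd.rbd_refine(
        img64,
        state.saliency_current,
        n_segments=cfg.superpixels_k,
        sigma_clr=cfg.sigma_clr,
        sigma_bndcon=cfg.sigma_bndcon,
        mu=cfg.mu,
    )
    if optimized.max() - optimized.min() <= 0.0:
        state.degenerate = True
        state.bw_curr = np.zeros(img64.shape[:2], dtype=np.uint8)
        state.history.append({"stage": "rbd", "degenerate": True})
    else:
        state.history.append({"stage": "rbd", "degenerate": False})
    state.saliency_current = optimized
    return state


def saturation_loop(
    state: PipelineState, img64: np.ndarray, cfg: PipelineConfig
) -> PipelineState:
    """Stage 4: iterate threshold -> similarity test -> learn until the
    perception saturates (consecutive masks with F >= f_stop)."""
    if state.degenerate:
        return state
    grad = gradient_magnitude(img64)
    sr_box_n = cfg.n_fixation
    best_prev = state.bw_prev
    for iteration in range(1, cfg.max_iter + 1):
        state.iteration = iteration
        bw = threshold_map(
            state.saliency_current,
            method=cfg.threshold_method,
            fixed=cfg.fixed_threshold,
            mean_std_k=cfg.mean_std_k,
        )
        area = int(bw.sum())
        if area == 0 or area == bw.size:
            # Divergent iterate: fall back to the best previous mask.
            state.diverged = True
            state.bw_curr = (
                best_prev if best_prev is not None
                else np.zeros(bw.shape, dtype=np.uint8)
            )
            state.history.append(
                {"iteration": iteration, "mask_area": area, "diverged": True}
            )
            return state
        similarity = None
        if state.bw_prev is not None:
            similarity = mask_similarity(bw, state.bw_prev, beta2=cfg.beta2)
        state.history.append(
            {
                "iteration": iteration,
                "mask_area": area,
                "similarity": similarity,
                "stimulus_count": state.stimulus_count,
            }
        )
        if similarity is not None and similarity >= cfg.f_stop:
            state.converged = True
            state.bw_curr = bw
            return state
        if iteration == cfg.max_iter:
            state.bw_curr = bw
            return state
        if cfg.loop_region == "mask":
            region = sampling.FixationRegion(kind="mask", mask=bw)
        else:
            region = sampling.top_n_box(state.saliency_current, n=sr_box_n)
        it_seed = cfg.seed + ITER_SEED_STRIDE * iteration
        try:
            stimuli = _learn_round(img64, region, cfg, grad, base_seed=it_seed)
        except ValueError:
            state.diverged = True
            state.bw_curr = bw
            state.history.append({"iteration": iteration, "diverged": True})
            return state
        _accumulate(state, stimuli)
        best_prev = bw
        state.bw_prev = bw
    return state


def segment(img: np.ndarray, cfg: PipelineConfig | None = None) -> SegmentResult:
    """Segment the salient object of an RGB image end to end.

    Returns the binary mask and saliency map at the original image geometry
    plus a per-iteration report; fully deterministic given ``cfg.seed``.
    Degenerate content (e.g. a featureless frame) yields a flagged empty
    mask rather than an exception.
    """
    if cfg is None:
        cfg = PipelineConfig()
    img = validate_rgb(img)
    h, w = img.shape[:2]
    img64 = downsample(img, target_side=cfg.work_side)
    state = coarse_saliency(img64, cfg)
    state = suppress_background(state, img64, cfg)
    state = saturation_loop(state, img64, cfg)
    if state.bw_curr is None:
        state.bw_curr = np.zeros(img64.shape[:2], dtype=np.uint8)
    mask = resize_mask_to(state.bw_curr, h, w)
    saliency = np.clip(
        _sk_resize(
            state.saliency_current,
            (h, w),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        ),
        0.0,
        1.0,
    )
    report = {
        "converged": state.converged,
        "degenerate": state.degenerate,
        "diverged": state.diverged,
        "iterations": state.iteration,
        "stimulus_count": state.stimulus_count,
        "history": state.history,
        "config": cfg.to_dict(),
    }
    return SegmentResult(mask=mask, saliency=saliency, report=report, state=state)
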