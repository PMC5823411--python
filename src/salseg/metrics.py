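"""Precision, recall, F-measure and PR curves for binary masks.

For a predicted mask M and ground truth G:

    P = |M & G| / |M|,   R = |M & G| / |G|,
    F = (1 + beta^2) P R / (beta^2 P + R)

with beta^2 = 0.3 by default, weighting precision over recall.  The same
F-measure serves both benchmark scoring and the feedback loop's saturation
test (similarity of consecutive fixation masks).

Empty-set conventions (flagged in the result): |M| = 0 gives P = 0 against a
nonempty truth; an empty truth met by an empty mask scores P = R = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np


@dataclass(frozen=True)
class EvalResult:
    """Per-image scores with the raw set cardinalities behind them."""

    precision: float
    recall: float
    f_measure: float
    beta2: float
    n_intersection: int
    n_mask: int
    n_truth: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask > 0


def f_measure(precision: float, recall: float, beta2: float = 0.3) -> float:
    """Weighted harmonic combination of precision and recall."""
    if beta2 < 0:
        raise ValueError(f"beta2 must be nonnegative, got {beta2}")
    if precision < 0 or precision > 1 or recall < 0 or recall > 1:
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = beta2 * precision + recall
    if denom == 0:
        return 0.0
    return (1.0 + beta2) * precision * recall / denom


def precision_recall(
    mask: np.ndarray, truth: np.ndarray, beta2: float = 0.3
) -> EvalResult:
    """Score a predicted mask against a ground-truth mask."""
    m = _as_bool(mask)
    g = _as_bool(truth)
    if m.shape != g.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs truth {g.shape}")
    n_inter = int((m & g).sum())
    n_mask = int(m.sum())
    n_truth = int(g.sum())
    flags: list[str] = []
    if n_truth == 0 and n_mask == 0:
        p = r = 1.0
        flags.append("both_empty")
    else:
        if n_mask == 0:
            p = 0.0
            flags.append("empty_mask")
        else:
            p = n_inter / n_mask
        if n_truth == 0:
            r = 0.0
            flags.append("empty_truth")
        else:
            r = n_inter / n_truth
    return EvalResult(
        precision=p,
        recall=r,
        f_measure=f_measure(p, r, beta2),
        beta2=beta2,
        n_intersection=n_inter,
        n_mask=n_mask,
        n_truth=n_truth,
        flags=tuple(flags),
    )


def pr_curve(
    saliency: np.ndarray, truth: np.ndarray, beta2: float = 0.3
) -> list[tuple[int, float, float]]:
    """PR points from fixed thresholds sweeping the 8-bit level range.

    The [0, 1] saliency map is quantized to integer levels 0-255; threshold
    t keeps pixels with level >= t, giving 256 (t, P, R) points.  Recall is
    nonincreasing in t.
    """
    saliency = np.asarray(saliency, dtype=np.float64)
    g = _as_bool(truth)
    if saliency.shape != g.shape:
        raise ValueError("saliency and truth shapes differ")
    levels = np.clip(np.rint(saliency * 255), 0, 255).astype(np.int64)
    hist_all = np.bincount(levels.ravel(), minlength=256)
    hist_true = np.bincount(levels[g], minlength=256)
    # Cumulative counts of pixels at level >= t.
    ge_all = np.cumsum(hist_all[::-1])[::-1]
    ge_true = np.cumsum(hist_true[::-1])[::-1]
    n_truth = int(g.sum())
    points = []
    for t in range(256):
        n_mask = int(ge_all[t])
        n_inter = int(ge_true[t])
        if n_truth == 0 and n_mask == 0:
            p = r = 1.0
        else:
            p = n_inter / n_mask if n_mask else 0.0
            r = n_inter / n_truth if n_truth else 0.0
        points.append((t, p, r))
    return points


def dataset_summary(results: list[EvalResult]) -> float:
    """Arithmetic mean F-measure over a dataset's per-image results."""
    if not results:
        raise ValueError("cannot summarize an empty result list")
    return float(np.mean([r.f_measure for r in results]))
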