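"""Polyharmonic extreme learning machine (PELM) and its ensemble (EPELM).

A PELM is a single-hidden-layer feedforward network whose inner weights are
drawn at random and never trained; only the output coefficients are fitted,
in closed form, by a Moore-Penrose pseudoinverse.  With L hidden nodes the
model output is

    f_r(x) = sum_i beta_i G(a_i, b_i, x) + P(x)

where G is the hidden-node activation (logistic sigmoid here) and P(x) a
low-degree (affine) polynomial trend that captures slow variation the random
features miss.  beta and the polynomial coefficients are fitted jointly from
the augmented design matrix [H | 1 | x], so the returned coefficients are the
least-squares optimum for the realised hidden layer.

An EPELM averages p independently seeded PELMs, f(x) = (1/p) sum_r f_r(x),
for a more stable decision.  Used here as an on-line pixel classifier on RGB
features with targets +1 (object) / -1 (background); each member's
sign-thresholded output over the image is one binary "stimulus".
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: Relative singular-value cutoff for the pseudoinverse.  RGB features are
#: low-dimensional and often collinear, so a rank-tolerant solve is needed.
PINV_RCOND = 1e-10

_ACTIVATIONS = {
    "sigmoid": expit,
}


@dataclass
class SampleSet:
    """Training pairs for the pixel classifier.

    ``features`` is (N, d) (RGB triples in [0, 1] in the pipeline), and
    ``targets`` is (N,) with the +1/-1 coding.  ``coords`` optionally keeps
    the (row, col) provenance of each sample for auditing.
    """

    features: np.ndarray
    targets: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        self.targets = np.asarray(self.targets, dtype=np.float64).ravel()
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValueError(
                f"features ({self.features.shape[0]}) and targets "
                f"({self.targets.shape[0]}) disagree in length"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class PELMModel:
    """A trained polyharmonic ELM; immutable after training."""

    inner_weights: np.ndarray   # (d, L)
    inner_biases: np.ndarray    # (L,)
    output_weights: np.ndarray  # (L,) beta
    poly_coeffs: np.ndarray     # (d + 1,) affine trend: [intercept, slopes]
    activation: str = "sigmoid"
    seed: int = 0

    @property
    def hidden_count(self) -> int:
        return self.inner_biases.shape[0]

    @property
    def dim(self) -> int:
        return self.inner_weights.shape[0]


@dataclass
class EPELMEnsemble:
    """Ensemble of p PELMs sharing feature dimension and target coding."""

    models: list[PELMModel] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.models)

    @property
    def dim(self) -> int:
        return self.models[0].dim


def _design_matrix(model_a: np.ndarray, model_b: np.ndarray, x: np.ndarray,
                   activation: str) -> np.ndarray:
    g = _ACTIVATIONS[activation]
    hidden = g(x @ model_a + model_b)
    ones = np.ones((x.shape[0], 1))
    return np.hstack([hidden, ones, x])


def train_pelm(samples: SampleSet, hidden_l: int = 20, seed: int = 0,
               activation: str = "sigmoid") -> PELMModel:
    """Train a PELM by a single pseudoinverse solve.

    Inner weights and biases are drawn from a seeded uniform(-1, 1); the
    output coefficients minimise the training sum of squared errors for the
    realised hidden layer.

    Raises
    ------
    ValueError
        If fewer than two samples or ``hidden_l < 1``.  A single-class
        target vector only warns: the affine trend absorbs constants.
    """
    if samples.n < 2:
        raise ValueError(f"need at least 2 training samples, got {samples.n}")
    if hidden_l < 1:
        raise ValueError(f"hidden_l must be >= 1, got {hidden_l}")
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    if np.unique(samples.targets).size < 2:
        warnings.warn(
            "all training targets identical; model degenerates to a constant",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    d = samples.dim
    a = rng.uniform(-1.0, 1.0, size=(d, hidden_l))
    b = rng.uniform(-1.0, 1.0, size=hidden_l)
    design = _design_matrix(a, b, samples.features, activation)
    coeffs = np.linalg.pinv(design, rcond=PINV_RCOND) @ samples.targets
    return PELMModel(
        inner_weights=a,
        inner_biases=b,
        output_weights=coeffs[:hidden_l],
        poly_coeffs=coeffs[hidden_l:],
        activation=activation,
        seed=seed,
    )


def predict(model: PELMModel, features: np.ndarray) -> np.ndarray:
    """Real-valued scores f_r(x) for an (N, d) feature array."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != model.dim:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model ({model.dim})"
        )
    g = _ACTIVATIONS[model.activation]
    hidden = g(x @ model.inner_weights + model.inner_biases)
    return hidden @ model.output_weights + model.poly_coeffs[0] + x @ model.poly_coeffs[1:]


def binarize(scores: np.ndarray) -> np.ndarray:
    """Map +1/-1-coded scores to {1, 0} labels; a score of exactly 0 is
    background (strict inequality avoids degenerate all-ones masks)."""
    scores = np.asarray(scores)
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    return (scores > 0).astype(np.uint8)


def train_ensemble(samples: SampleSet, p: int = 3, hidden_l: int = 20,
                   seed: int = 0, activation: str = "sigmoid") -> EPELMEnsemble:
    """Train p PELMs with seeds ``seed, seed+1, ..., seed+p-1``."""
    if p < 1:
        raise ValueError(f"ensemble size p must be >= 1, got {p}")
    models = [
        train_pelm(samples, hidden_l=hidden_l, seed=seed + r, activation=activation)
        for r in range(p)
    ]
    return EPELMEnsemble(models=models)


def ensemble_predict(ensemble: EPELMEnsemble, features: np.ndarray) -> np.ndarray:
    """Averaged score f(x) = (1/p) sum_r f_r(x)."""
    if ensemble.p < 1:
        raise ValueError("empty ensemble")
    scores = np.stack([predict(m, features) for m in ensemble.models])
    return scores.mean(axis=0)


def classify_image(
    ensemble: EPELMEnsemble, img: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    """Classify every pixel of an (H, W, d) image.

    Returns ``(stimuli, ensemble_mask)``: one binary stimulus mask per
    ensemble member plus the sign-threshold of the averaged score.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != ensemble.dim:
        raise ValueError(
            f"image channels {img.shape} do not match feature dimension "
            f"{ensemble.dim}"
        )
    h, w, d = img.shape
    flat = img.reshape(-1, d)
    per_model = [predict(m, flat) for m in ensemble.models]
    stimuli = [binarize(s).reshape(h, w) for s in per_model]
    mean_score = np.mean(per_model, axis=0)
    ensemble_mask = binarize(mean_score).reshape(h, w)
    return stimuli, ensemble_mask


# --- serialization ---------------------------------------------------------

def model_to_dict(model: PELMModel) -> dict:
    return {
        "inner_weights": model.inner_weights.tolist(),
        "inner_biases": model.inner_biases.tolist(),
        "output_weights": model.output_weights.tolist(),
        "poly_coeffs": model.poly_coeffs.tolist(),
        "activation": model.activation,
        "seed": model.seed,
    }


def model_from_dict(doc: dict) -> PELMModel:
    return PELMModel(
        inner_weights=np.asarray(doc["inner_weights"], dtype=np.float64),
        inner_biases=np.asarray(doc["inner_biases"], dtype=np.float64),
        output_weights=np.asarray(doc["output_weights"], dtype=np.float64),
        poly_coeffs=np.asarray(doc["poly_coeffs"], dtype=np.float64),
        activation=doc.get("activation", "sigmoid"),
        seed=int(doc.get("seed", 0)),
    )


def save_ensemble(path: str | os.PathLike, ensemble: EPELMEnsemble) -> None:
    doc = {"p": ensemble.p, "models": [model_to_dict(m) for m in ensemble.models]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_ensemble(path: str | os.PathLike) -> EPELMEnsemble:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return EPELMEnsemble(models=[model_from_dict(m) for m in doc["models"]])
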