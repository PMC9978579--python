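"""Autoencoder and batch-classifier construction.

Preprocessing is log10 followed by per-feature standardization; the inverse
transform (de-standardize, exponentiate) guarantees strictly positive outputs
on the intensity scale.  The bottleneck width defaults to the number of
principal components of the preprocessed matrix needed to reach the requested
cumulative explained-variance ratio.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.decomposition import PCA

from ._autograd import Tensor

__all__ = ["Preprocessor", "ModelSpec", "MLP", "select_latent_dim", "build_models"]

_EXP_CLIP = 18.0  # clamp log10 intensities on inverse transform to avoid overflow


class Preprocessor:
    """log10 + per-feature z-score, with exact strictly-positive inverse."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "Preprocessor":
        if np.any(~np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("preprocessing requires finite, strictly positive values")
        logv = np.log10(values)
        self.mean_ = logv.mean(axis=0)
        std = logv.std(axis=0)
        self.std_ = np.where(std > 0, std, 1.0)  # constant features stay put
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.log10(values) - self.mean_) / self.std_

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        logv = np.clip(z * self.std_ + self.mean_, -_EXP_CLIP, _EXP_CLIP)
        return 10.0**logv

    def inverse_tensor(self, z: Tensor) -> Tensor:
        """Differentiable inverse used by the variation loss."""
        logv = (z * Tensor(self.std_) + Tensor(self.mean_)).clip(-_EXP_CLIP, _EXP_CLIP)
        return (logv * np.log(10.0)).exp()


def select_latent_dim(preprocessed: np.ndarray, variance_ratio: float) -> int:
    """Smallest k whose top-k principal components explain >= variance_ratio.

    Operates on the preprocessed (log, standardized) matrix so that variance
    is on correlation scale rather than dominated by high-intensity features.
    """
    if not (0.0 < variance_ratio <= 1.0):
        raise ValueError("variance_ratio must be in (0, 1]")
    X = np.asarray(preprocessed, dtype=np.float64)
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("matrix has zero total variance; cannot size the bottleneck")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cumulative, variance_ratio - 1e-12) + 1)
    return min(k, len(cumulative))


@dataclass
class ModelSpec:
    """Layer layout shared by encoder, decoder and classifier."""

    n_features: int
    latent_dim: int
    n_batches: int
    activation: str = "leaky_relu"

    def __post_init__(self) -> None:
        if not (1 <= self.latent_dim <= self.n_features):
            raise ValueError("latent_dim must be in [1, n_features]")
        if self.n_batches < 2:
            raise ValueError("classifier needs at least 2 batches")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class MLP:
    """Single-hidden-layer perceptron with leaky-ReLU, on the autodiff core."""

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        n_out: int,
        rng: np.random.Generator,
        final_linear: bool = True,
    ):
        def he(n_i, n_o):
            return Tensor(rng.normal(0.0, np.sqrt(2.0 / n_i), (n_i, n_o)), requires_grad=True)

        self.w1 = he(n_in, n_hidden)
        self.b1 = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.w2 = he(n_hidden, n_out)
        self.b2 = Tensor(np.zeros(n_out), requires_grad=True)
        self.final_linear = final_linear

    @property
    def params(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        h = (x @ self.w1 + self.b1).leaky_relu()
        out = h @ self.w2 + self.b2
        return out if self.final_linear else out.leaky_relu()

    def forward_array(self, x: np.ndarray) -> np.ndarray:
        return self(Tensor(x)).data

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data = s.copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_models(spec: ModelSpec, seed: int) -> tuple[MLP, MLP, MLP]:
    """Seeded (encoder, decoder, classifier) triple.

    Encoder: n_features -> latent -> latent; decoder mirrors it back to
    n_features; classifier maps latent codes to batch logits (apply
    :func:`softmax` for probabilities).
    """
    rng = np.random.default_rng(seed)
    encoder = MLP(spec.n_features, spec.latent_dim, spec.latent_dim, rng)
    decoder = MLP(spec.latent_dim, spec.latent_dim, spec.n_features, rng)
    classifier = MLP(spec.latent_dim, spec.latent_dim, spec.n_batches, rng)
    return encoder, decoder, classifier
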