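"""The three loss terms and their aggregation.

L = lambda_g * (reconstruction + r_g) - lambda_d * L_d + lambda_v * L_v

The classifier term enters the autoencoder objective with a negative sign
(adversarial); the classifier itself is trained to minimize L_d on the same
latent codes in alternating steps.  r_g is a clustering-based reward in
[0, 1] evaluated with UMAP + HDBSCAN and is not differentiated; a
distance-based differentiable alternative is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, cross_entropy

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "reconstruction_loss",
    "grouping_term",
    "grouping_term_distance",
    "classifier_loss",
    "variation_loss",
    "aggregate",
    "group_batch_cells",
]


@dataclass
class LossWeights:
    lambda_g: float = 1.0
    lambda_d: float = 1.0
    lambda_v: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_g", "lambda_d", "lambda_v"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass
class LossBreakdown:
    """Per-epoch record of every term plus the aggregate."""

    reconstruction: float
    r_g: float
    l_d: float
    l_v: float
    total: float
    classifier_accuracy: float = float("nan")
    output_variance_ratio: float = float("nan")


def reconstruction_loss(x, x_hat, kind: str = "mse"):
    """Mean squared (or absolute) error over all cells; Tensor-aware."""
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if isinstance(x, Tensor) or isinstance(x_hat, Tensor):
        x = x if isinstance(x, Tensor) else Tensor(x)
        x_hat = x_hat if isinstance(x_hat, Tensor) else Tensor(x_hat)
        diff = x - x_hat
        return (diff * diff).mean() if kind == "mse" else diff.abs().mean()
    diff = np.asarray(x) - np.asarray(x_hat)
    return float((diff**2).mean()) if kind == "mse" else float(np.abs(diff).mean())


def _same_group_pairs(groups: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    for g in dict.fromkeys(groups):  # preserves order
        if not g:
            continue
        idx = np.flatnonzero(groups == g)
        pairs.extend((int(i), int(j)) for a, i in enumerate(idx) for j in idx[a + 1 :])
    return pairs


def grouping_term(
    embedding: np.ndarray,
    groups: np.ndarray,
    *,
    min_cluster_size: int | None = None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    random_state: int = 0,
) -> float:
    """Clustering reward r_g in [0, 1]; 0 at perfect co-clustering.

    All samples are flattened to 2-D with UMAP, clustered with HDBSCAN
    (noise points count as their own singleton clusters), and r_g is the
    fraction of same-group reference-sample pairs NOT assigned to the same
    cluster.
    """
    groups = np.asarray(groups, dtype=object)
    pairs = _same_group_pairs(groups)
    if not pairs:
        warnings.warn("no evaluable reference pairs; r_g set to 0", stacklevel=2)
        return 0.0

    import umap  # deferred: slow import (numba)
    from sklearn.cluster import HDBSCAN

    X = np.asarray(embedding, dtype=np.float64)
    n = X.shape[0]
    if min_cluster_size is None:
        sizes = [np.sum(groups == g) for g in set(groups) if g]
        min_cluster_size = max(2, int(min(sizes)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=min(n_neighbors, n - 1),
            min_dist=min_dist,
            random_state=random_state,
        )
        flat = reducer.fit_transform(X)
        labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(flat)
    # noise (-1) becomes a unique singleton cluster per sample
    labels = labels.astype(np.int64)
    noise = labels == -1
    labels[noise] = labels.max() + 1 + np.arange(int(noise.sum()))
    together = sum(labels[i] == labels[j] for i, j in pairs)
    return 1.0 - together / len(pairs)


def grouping_term_distance(latent, groups: np.ndarray):
    """Scale-free distance alternative to r_g (differentiable when given a Tensor).

    Mean pairwise Euclidean distance over same-group reference pairs divided
    by the mean pairwise distance over all sample pairs; 0 when replicates
    coincide, ~1 when they scatter like everything else.
    """
    groups = np.asarray(groups, dtype=object)
    pairs = _same_group_pairs(groups)
    if not pairs:
        warnings.warn("no evaluable reference pairs; distance term set to 0", stacklevel=2)
        return 0.0 if not isinstance(latent, Tensor) else Tensor(0.0)

    data = latent.data if isinstance(latent, Tensor) else np.asarray(latent, dtype=np.float64)
    n = data.shape[0]
    sq = (data**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * data @ data.T, 0.0)
    iu = np.triu_indices(n, k=1)
    denom = float(np.sqrt(d2[iu]).mean())
    if denom == 0.0:
        return 0.0 if not isinstance(latent, Tensor) else Tensor(0.0)

    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    if isinstance(latent, Tensor):
        diff = latent.take_rows(ii) - latent.take_rows(jj)
        dist = ((diff * diff).sum(axis=1) + 1e-12).sqrt()
        return dist.mean() / denom
    return float(np.sqrt(((data[ii] - data[jj]) ** 2).sum(axis=1)).mean()) / denom


def classifier_loss(logits, labels: np.ndarray):
    """Multiclass cross-entropy of batch predictions from raw logits."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("classifier loss requires labels from >= 2 batches")
    if isinstance(logits, Tensor):
        return cross_entropy(logits, labels)
    return float(cross_entropy(Tensor(np.asarray(logits, dtype=np.float64)), labels).data)


def group_batch_cells(groups: np.ndarray, batches: np.ndarray) -> list[np.ndarray]:
    """Index sets of replicate samples, one per (reference group, batch) with >= 2 members."""
    groups = np.asarray(groups, dtype=object)
    batches = np.asarray(batches, dtype=object)
    cells = []
    for g in dict.fromkeys(groups):
        if not g:
            continue
        for b in dict.fromkeys(batches):
            idx = np.flatnonzero((groups == g) & (batches == b))
            if len(idx) >= 2:
                cells.append(idx)
    return cells


def variation_loss(x_hat_intensity, groups: np.ndarray, batches: np.ndarray):
    """Mean variation coefficient (sd/mean, ddof=1) of reconstructed replicate
    intensities over all (reference group, batch, feature) cells; Tensor-aware.
    """
    cells = group_batch_cells(groups, batches)
    if not cells:
        raise ValueError("no (group, batch) cell with >= 2 replicate samples")
    if isinstance(x_hat_intensity, Tensor):
        total = Tensor(0.0)
        count = 0
        for idx in cells:
            block = x_hat_intensity.take_rows(idx)
            n = len(idx)
            mu = block.mean(axis=0)
            dev = block - mu
            sd = ((dev * dev).sum(axis=0) / (n - 1) + 1e-300).sqrt()
            vc = sd / mu
            total = total + vc.sum()
            count += block.shape[1]
        return total / count
    x = np.asarray(x_hat_intensity, dtype=np.float64)
    vcs = []
    for idx in cells:
        block = x[idx]
        vcs.append(block.std(axis=0, ddof=1) / block.mean(axis=0))
    return float(np.concatenate(vcs).mean())


def aggregate(reconstruction, r_g, l_d, l_v, weights: LossWeights):
    """Aggregate autoencoder objective; Tensor-aware.

    The classifier term is subtracted so that a successful batch classifier
    penalizes the autoencoder.
    """
    return (
        weights.lambda_g * (reconstruction + r_g)
        - weights.lambda_d * l_d
        + weights.lambda_v * l_v
    )
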