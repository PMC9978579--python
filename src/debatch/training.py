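"""Adversarial training loop, early stopping, randomized grid search and
model selection.

Each minibatch takes one (or ``d_steps_per_g_step``) classifier update(s)
minimizing the batch cross-entropy on detached latent codes, followed by one
autoencoder update minimizing the aggregate objective

    L = lambda_g * (reconstruction + r_g) - lambda_d * L_d + lambda_v * L_v.

The clustering reward r_g (UMAP + HDBSCAN) is refreshed on the full dataset
every ``rg_every`` epochs and enters the objective as a constant; with
``grouping_method="distance"`` a differentiable latent-distance surrogate is
used per minibatch instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._autograd import Adam, Tensor, cross_entropy
from .data_io import BatchInfo, IntensityMatrix, RunConfig
from .evaluation import EvaluationReport, evaluate
from .losses import (
    LossBreakdown,
    LossWeights,
    aggregate,
    group_batch_cells,
    grouping_term,
    grouping_term_distance,
    reconstruction_loss,
    variation_loss,
)
from .network import ModelSpec, Preprocessor, build_models, select_latent_dim, softmax

__all__ = [
    "HyperParams",
    "NormalizationResult",
    "train",
    "early_stop_check",
    "grid_search",
    "sample_grid",
    "select_best",
    "history_frame",
]

CONTINUE = "continue"
COMPLETED = "completed"
STOP_CLASSIFIER = "early_stop_classifier"
STOP_COLLAPSE = "early_stop_collapse"
FAILED = "failed_nonfinite"


@dataclass
class HyperParams:
    weights: LossWeights = field(default_factory=LossWeights)
    lr_autoencoder: float = 5e-3
    lr_classifier: float = 5e-3
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    variance_ratio: float = 0.9
    latent_dim: int | None = None  # overrides the PCA rule when set

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_autoencoder <= 0 or self.lr_classifier <= 0:
            raise ValueError("learning rates must be > 0")


@dataclass
class NormalizationResult:
    normalized: IntensityMatrix | None
    history: list[LossBreakdown]
    stop_reason: str
    hyperparams: HyperParams
    latent_dim: int
    evaluation: EvaluationReport | None = None

    @property
    def failed(self) -> bool:
        return self.normalized is None


def early_stop_check(
    history: list[LossBreakdown],
    window: int = 5,
    patience: int = 5,
    collapse_ratio: float = 1e-3,
) -> str:
    """Stop when the classifier loss rose monotonically for ``patience``
    consecutive epochs, or when the reconstruction variance collapsed below
    ``collapse_ratio`` times the input variance.  No signal before ``window``
    epochs of history.
    """
    if len(history) < window:
        return CONTINUE
    if len(history) > patience:
        tail = [h.l_d for h in history[-(patience + 1) :]]
        if all(b > a for a, b in zip(tail, tail[1:])):
            return STOP_CLASSIFIER
    if history[-1].output_variance_ratio < collapse_ratio:
        return STOP_COLLAPSE
    return CONTINUE


def _epoch_record(
    Z: np.ndarray,
    y: np.ndarray,
    encoder,
    decoder,
    classifier,
    prep: Preprocessor,
    groups: np.ndarray,
    batches: np.ndarray,
    r_g: float,
    weights: LossWeights,
    kind: str,
    has_cells: bool,
) -> LossBreakdown:
    z = encoder.forward_array(Z)
    xh = decoder.forward_array(z)
    logits = classifier.forward_array(z)
    recon = reconstruction_loss(Z, xh, kind)
    l_d = float(cross_entropy(Tensor(logits), y).data)
    acc = float((logits.argmax(axis=1) == y).mean())
    l_v = (
        variation_loss(prep.inverse(xh), groups, batches) if has_cells else 0.0
    )
    total = float(aggregate(recon, r_g, l_d, l_v, weights))
    var_in = float(Z.var())
    var_ratio = float(xh.var() / var_in) if var_in > 0 else float("nan")
    return LossBreakdown(recon, r_g, l_d, l_v, total, acc, var_ratio)


def train(
    m: IntensityMatrix,
    b: BatchInfo,
    hp: HyperParams,
    config: RunConfig | None = None,
) -> NormalizationResult:
    """Run one adversarial normalization; deterministic for fixed hp + seed
    (single-threaded).  ``m`` must already have the minimum-intensity rule
    applied (strictly positive values).
    """
    cfg = config or RunConfig()
    b = b.align(m.sample_ids)
    y = b.batch_codes()
    n_batches = int(y.max()) + 1
    groups, batches = b.groups, b.batches

    prep = Preprocessor().fit(m.values)
    Z = prep.transform(m.values)
    latent_dim = hp.latent_dim or cfg.latent_dim or select_latent_dim(Z, hp.variance_ratio)
    spec = ModelSpec(m.n_features, latent_dim, n_batches)
    encoder, decoder, classifier = build_models(spec, hp.seed)
    opt_ae = Adam(encoder.params + decoder.params, lr=hp.lr_autoencoder)
    opt_cls = Adam(classifier.params, lr=hp.lr_classifier)

    has_cells = bool(group_batch_cells(groups, batches))
    if hp.weights.lambda_v > 0 and not has_cells:
        warnings.warn(
            "no (group, batch) replicate cells; variation loss disabled", stacklevel=2
        )

    rng = np.random.default_rng(hp.seed)
    n = m.n_samples
    batch_size = min(hp.batch_size, n)
    r_g_cached = 0.0
    history: list[LossBreakdown] = []
    stop_reason = COMPLETED

    for epoch in range(hp.epochs):
        if cfg.grouping_method == "cluster" and hp.weights.lambda_g > 0:
            if epoch % max(1, cfg.rg_every) == 0:
                latent_full = encoder.forward_array(Z)
                r_g_cached = grouping_term(latent_full, groups, random_state=hp.seed)
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = Tensor(Z[idx])
            yb = y[idx]
            # classifier step(s) on detached latent codes
            if len(set(yb.tolist())) >= 2:
                for _ in range(max(1, cfg.d_steps_per_g_step)):
                    z_det = Tensor(encoder(xb).data)
                    loss_d = cross_entropy(classifier(z_det), yb)
                    opt_cls.zero_grad()
                    loss_d.backward()
                    opt_cls.step()
            # autoencoder step
            z = encoder(xb)
            x_hat = decoder(z)
            recon = reconstruction_loss(xb, x_hat, cfg.reconstruction_loss)
            if cfg.grouping_method == "distance" and hp.weights.lambda_g > 0:
                r_g_term = grouping_term_distance(z, groups[idx])
            else:
                r_g_term = r_g_cached
            l_d_term = (
                cross_entropy(classifier(z), yb)
                if hp.weights.lambda_d > 0 and len(set(yb.tolist())) >= 2
                else 0.0
            )
            if hp.weights.lambda_v > 0 and group_batch_cells(groups[idx], batches[idx]):
                l_v_term = variation_loss(
                    prep.inverse_tensor(x_hat), groups[idx], batches[idx]
                )
            else:
                l_v_term = 0.0
            loss = aggregate(recon, r_g_term, l_d_term, l_v_term, hp.weights)
            opt_ae.zero_grad()
            opt_cls.zero_grad()
            loss.backward()
            opt_ae.step()

        record = _epoch_record(
            Z, y, encoder, decoder, classifier, prep, groups, batches,
            r_g_cached, hp.weights, cfg.reconstruction_loss, has_cells,
        )
        history.append(record)
        if not all(
            np.isfinite(v) for v in (record.reconstruction, record.l_d, record.l_v)
        ):
            return NormalizationResult(None, history, FAILED, hp, latent_dim)
        decision = early_stop_check(history, cfg.window, cfg.patience, cfg.collapse_ratio)
        if decision != CONTINUE:
            stop_reason = decision
            break

    x_hat_full = decoder.forward_array(encoder.forward_array(Z))
    values = prep.inverse(x_hat_full)
    if not np.all(np.isfinite(values)):
        return NormalizationResult(None, history, FAILED, hp, latent_dim)
    normalized = IntensityMatrix(list(m.sample_ids), list(m.feature_ids), values)
    try:
        report = evaluate(m, normalized, b, seed=hp.seed)
    except ValueError:
        report = None
    return NormalizationResult(normalized, history, stop_reason, hp, latent_dim, report)


def sample_grid(config: RunConfig) -> list[HyperParams]:
    """Draw ``grid_size`` hyperparameter sets; log-uniform in the configured
    ranges; deterministic for a fixed master seed.
    """
    rng = np.random.default_rng(config.seed)

    def log_uniform(lo: float, hi: float) -> float:
        if lo == hi:
            return float(lo)
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    out = []
    for _ in range(config.grid_size):
        weights = LossWeights(
            lambda_g=log_uniform(*config.lambda_g_range),
            lambda_d=log_uniform(*config.lambda_d_range),
            lambda_v=log_uniform(*config.lambda_v_range),
        )
        out.append(
            HyperParams(
                weights=weights,
                lr_autoencoder=log_uniform(*config.lr_range),
                lr_classifier=log_uniform(*config.lr_range),
                epochs=config.epochs,
                batch_size=config.batch_size,
                seed=int(rng.integers(0, 2**31 - 1)),
                variance_ratio=config.variance_ratio,
                latent_dim=config.latent_dim,
            )
        )
    return out


def grid_search(
    m: IntensityMatrix, b: BatchInfo, config: RunConfig
) -> list[NormalizationResult]:
    """Train one model per sampled hyperparameter set.  Individual failed
    runs are kept in the output (stop_reason records why) but are excluded
    from selection.
    """
    grid = sample_grid(config)
    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=config.n_jobs)(
            delayed(train)(m, b, hp, config) for hp in grid
        )
    return [train(m, b, hp, config) for hp in grid]


def _selection_metrics(r: NormalizationResult) -> tuple:
    e = r.evaluation
    return (
        e.between_batch_corr.get("mean", float("nan")),
        e.mean_batch_vc,
        e.vc_inflation_fraction,
        e.batch_mixing.excess,
    )


def select_best(
    results: list[NormalizationResult],
) -> tuple[NormalizationResult, pd.DataFrame]:
    """Rank candidates by the sum of ranks over four criteria: higher mean
    between-batch replicate correlation, lower mean batch VC, lower
    VC-inflation fraction, and probe accuracy closest to chance.  Ties break
    on the first criterion.  Returns the winner and the full ranking table.
    """
    ok = [r for r in results if not r.failed and r.evaluation is not None]
    if not ok:
        raise ValueError("all runs failed; nothing to select")
    metrics = np.array([_selection_metrics(r) for r in ok])
    ranks = np.column_stack(
        [
            rankdata(-metrics[:, 0]),  # between-batch corr: higher is better
            rankdata(metrics[:, 1]),  # mean batch VC: lower
            rankdata(metrics[:, 2]),  # VC inflation: lower
            rankdata(metrics[:, 3]),  # |accuracy - chance|: lower
        ]
    )
    rank_sum = ranks.sum(axis=1)
    order = np.lexsort((-metrics[:, 0], rank_sum))
    best = ok[int(order[0])]

    rows = []
    ok_pos = {id(r): i for i, r in enumerate(ok)}
    for r in results:
        i = ok_pos.get(id(r))
        row = {
            "lambda_g": r.hyperparams.weights.lambda_g,
            "lambda_d": r.hyperparams.weights.lambda_d,
            "lambda_v": r.hyperparams.weights.lambda_v,
            "lr_autoencoder": r.hyperparams.lr_autoencoder,
            "lr_classifier": r.hyperparams.lr_classifier,
            "seed": r.hyperparams.seed,
            "latent_dim": r.latent_dim,
            "stop_reason": r.stop_reason,
            "epochs_run": len(r.history),
        }
        if i is not None:
            row.update(
                between_corr_mean=metrics[i, 0],
                mean_batch_vc=metrics[i, 1],
                vc_inflation=metrics[i, 2],
                mixing_excess=metrics[i, 3],
                rank_sum=rank_sum[i],
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        "rank_sum", na_position="last", kind="stable"
    )
    return best, table


def history_frame(result: NormalizationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch": np.arange(1, len(result.history) + 1),
            "L_g": [h.reconstruction for h in result.history],
            "r_g": [h.r_g for h in result.history],
            "L_d": [h.l_d for h in result.history],
            "L_v": [h.l_v for h in result.history],
            "L": [h.total for h in result.history],
            "classifier_accuracy": [h.classifier_accuracy for h in result.history],
            "output_variance_ratio": [h.output_variance_ratio for h in result.history],
        }
    )
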