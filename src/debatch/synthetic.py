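"""Synthetic multi-batch intensity data with known ground truth.

The generative model is multiplicative on the intensity scale:

    observed[s, f] = true[s, f] * batch_factor[batch(s), f] * noise[s, f]

with log-normal base intensities spanning several orders of magnitude,
per-(batch, feature) multiplicative batch effects, log-normal measurement
noise of a given coefficient of variation, and detection-limit censoring
(cells below ``censor_threshold`` are emitted as missing).  All members of a
reference group share a single true profile, so their observed differences
are entirely batch effect plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import BatchInfo, IntensityMatrix, ValidationError

__all__ = [
    "ReferenceGroupSpec",
    "SimulationDesign",
    "GroundTruth",
    "simulate",
    "ablate",
]


@dataclass
class ReferenceGroupSpec:
    """A reference group: replicated samples present in a subset of batches."""

    name: str
    replicates_per_batch: int = 3
    batches: list[int] | None = None  # None = present in every batch


@dataclass
class SimulationDesign:
    n_batches: int = 5
    n_features: int = 60
    reference_groups: list[ReferenceGroupSpec] = field(
        default_factory=lambda: [
            ReferenceGroupSpec("QC1", 3),
            ReferenceGroupSpec("QC2", 3),
        ]
    )
    n_nonreference_samples: int = 10  # per batch
    log10_mean: float = 5.0
    log10_sd: float = 1.0
    batch_log_sd: float = 0.8  # natural-log sd of per-(batch, feature) factor
    noise_cv: float = 0.1  # multiplicative measurement noise CV
    censor_threshold: float = 0.0  # counts; cells below become missing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValidationError("n_batches must be >= 2")
        if self.batch_log_sd < 0 or self.log10_sd < 0 or self.noise_cv < 0:
            raise ValidationError("spread parameters must be >= 0")
        if self.censor_threshold < 0:
            raise ValidationError("censor_threshold must be >= 0")


@dataclass
class GroundTruth:
    true_matrix: np.ndarray  # batch-free intensities, samples x features
    batch_factors: np.ndarray  # n_batches x n_features multiplicative factors
    noise_factors: np.ndarray  # samples x features multiplicative noise


def _draw_profile(rng: np.random.Generator, design: SimulationDesign) -> np.ndarray:
    return 10.0 ** rng.normal(design.log10_mean, design.log10_sd, design.n_features)


def simulate(design: SimulationDesign) -> tuple[IntensityMatrix, BatchInfo, GroundTruth]:
    """Generate one seeded dataset; bit-reproducible for a fixed design."""
    rng = np.random.default_rng(design.seed)
    batch_factors = np.exp(
        rng.normal(0.0, design.batch_log_sd, (design.n_batches, design.n_features))
    )
    group_profiles = {g.name: _draw_profile(rng, design) for g in design.reference_groups}
    # lognormal with CV c has log-sd sqrt(ln(1 + c^2))
    noise_sd = float(np.sqrt(np.log1p(design.noise_cv**2)))

    sample_ids: list[str] = []
    batches: list[str] = []
    groups: list[str] = []
    true_rows: list[np.ndarray] = []
    batch_idx: list[int] = []
    for bi in range(design.n_batches):
        bname = f"B{bi + 1}"
        for g in design.reference_groups:
            if g.batches is not None and bi not in g.batches:
                continue
            for r in range(g.replicates_per_batch):
                sample_ids.append(f"{g.name}_{bname}_r{r + 1}")
                batches.append(bname)
                groups.append(g.name)
                true_rows.append(group_profiles[g.name])
                batch_idx.append(bi)
        for i in range(design.n_nonreference_samples):
            sample_ids.append(f"S_{bname}_{i + 1}")
            batches.append(bname)
            groups.append("")
            true_rows.append(_draw_profile(rng, design))
            batch_idx.append(bi)

    true = np.vstack(true_rows)
    noise = np.exp(rng.normal(0.0, noise_sd, true.shape)) if noise_sd > 0 else np.ones_like(true)
    observed = true * batch_factors[np.asarray(batch_idx)] * noise
    observed = np.where(observed < design.censor_threshold, np.nan, observed)

    feature_ids = [f"F{j + 1:04d}" for j in range(design.n_features)]
    m = IntensityMatrix(sample_ids, feature_ids, observed)
    b = BatchInfo(sample_ids, np.asarray(batches, dtype=object), np.asarray(groups, dtype=object))
    truth = GroundTruth(true, batch_factors, noise)
    return m, b, truth


def ablate(
    m: IntensityMatrix,
    b: BatchInfo,
    mode: str,
    amount,
    seed: int | None = None,
) -> tuple[IntensityMatrix, BatchInfo]:
    """Degrade a dataset for robustness experiments.

    mode="drop_batches"   amount = number of latest batches to remove
                          (chronology = batch order of first appearance)
    mode="drop_features"  amount = fraction of features to RETAIN in (0, 1];
                          round(amount * n_features) random features survive
    mode="inject_missing" amount = fraction of cells in [0, 1] replaced by the
                          missing marker at random positions
    """
    aligned = b.align(m.sample_ids)
    if mode == "drop_batches":
        n_drop = int(amount)
        order = aligned.batch_order
        if n_drop < 0 or len(order) - n_drop < 2:
            raise ValidationError(
                f"dropping {n_drop} of {len(order)} batches leaves fewer than 2"
            )
        if n_drop == 0:
            return m.copy(), aligned
        keep_batches = set(order[: len(order) - n_drop])
        keep = np.flatnonzero([bt in keep_batches for bt in aligned.batches])
        sub = IntensityMatrix(
            [m.sample_ids[i] for i in keep], list(m.feature_ids), m.values[keep]
        )
        return sub, aligned.subset(keep)

    if mode == "drop_features":
        frac = float(amount)
        if not (0 < frac <= 1):
            raise ValidationError("retention fraction must be in (0, 1]")
        n_keep = int(round(frac * m.n_features))
        if n_keep < 1:
            raise ValidationError("feature removal would leave 0 features")
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(m.n_features, size=n_keep, replace=False))
        sub = IntensityMatrix(
            list(m.sample_ids), [m.feature_ids[j] for j in keep], m.values[:, keep]
        )
        return sub, aligned

    if mode == "inject_missing":
        frac = float(amount)
        if not (0 <= frac <= 1):
            raise ValidationError("missing fraction must be in [0, 1]")
        values = m.values.copy()
        n_cells = values.size
        n_pick = int(round(frac * n_cells))
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_cells, size=n_pick, replace=False)
        values.flat[flat] = np.nan
        return IntensityMatrix(list(m.sample_ids), list(m.feature_ids), values), aligned

    raise ValidationError(f"unknown ablation mode: {mode!r}")
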