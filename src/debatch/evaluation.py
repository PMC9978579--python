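"""Evaluation metrics: replicate cross-correlation, batch variation
coefficients, VC inflation, batch mixing and spectra preservation.

All metrics are pure functions of their inputs (plus explicit seeds).
Correlations are computed on log10 intensities so low-abundance features
contribute; VCs are computed per (reference group, batch, feature) so that
genuinely different samples never inflate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler

from .data_io import BatchInfo, IntensityMatrix
from .losses import group_batch_cells

__all__ = [
    "EvaluationReport",
    "BatchMixing",
    "SpectraShift",
    "replicate_correlations",
    "batch_vc",
    "vc_inflation",
    "batch_mixing",
    "spectra_shift",
    "evaluate",
]


def _summary(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {"n": 0, "mean": float("nan"), "median": float("nan")}
    q = np.quantile(values, [0.05, 0.25, 0.75, 0.95])
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "median": float(np.median(values)),
        "q05": float(q[0]),
        "q25": float(q[1]),
        "q75": float(q[2]),
        "q95": float(q[3]),
    }


@dataclass
class BatchMixing:
    accuracy: float
    chance: float

    @property
    def excess(self) -> float:
        """Distance from chance; ~0 means batches are indistinguishable."""
        return abs(self.accuracy - self.chance)


@dataclass
class SpectraShift:
    rank_correlation: float
    max_z_displacement: float


@dataclass
class EvaluationReport:
    within_batch_corr: dict = field(default_factory=dict)
    between_batch_corr: dict = field(default_factory=dict)
    mean_batch_vc: float = float("nan")
    vc_inflation_fraction: float = float("nan")
    batch_mixing: BatchMixing | None = None
    spectra_shift: SpectraShift | None = None

    def to_dict(self) -> dict:
        return {
            "within_batch_corr": self.within_batch_corr,
            "between_batch_corr": self.between_batch_corr,
            "mean_batch_vc": self.mean_batch_vc,
            "vc_inflation_fraction": self.vc_inflation_fraction,
            "batch_mixing": None
            if self.batch_mixing is None
            else {
                "accuracy": self.batch_mixing.accuracy,
                "chance": self.batch_mixing.chance,
            },
            "spectra_shift": None
            if self.spectra_shift is None
            else {
                "rank_correlation": self.spectra_shift.rank_correlation,
                "max_z_displacement": self.spectra_shift.max_z_displacement,
            },
        }


def replicate_correlations(
    m: IntensityMatrix, b: BatchInfo, log_scale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r over the feature vector for every same-group sample pair,
    split into (within-batch, between-batch) arrays.
    """
    b = b.align(m.sample_ids)
    X = np.log10(m.values) if log_scale else m.values
    within, between = [], []
    for _, idx in b.reference_groups().items():
        if len(idx) < 2:
            continue
        for a in range(len(idx)):
            for c in range(a + 1, len(idx)):
                i, j = idx[a], idx[c]
                r = float(np.corrcoef(X[i], X[j])[0, 1])
                (within if b.batches[i] == b.batches[j] else between).append(r)
    if not within and not between:
        raise ValueError("no evaluable replicate pairs")
    return np.asarray(within), np.asarray(between)


def batch_vc(m: IntensityMatrix, b: BatchInfo) -> tuple[pd.DataFrame, float]:
    """Per-(batch, group, feature) VC table (sd/mean over replicate samples,
    intensity scale, ddof=1) and its grand mean.
    """
    b = b.align(m.sample_ids)
    rows = []
    for g, gidx in b.reference_groups().items():
        for batch in b.batch_order:
            idx = gidx[np.asarray([b.batches[i] == batch for i in gidx])]
            if len(idx) < 2:
                continue
            block = m.values[idx]
            vc = block.std(axis=0, ddof=1) / block.mean(axis=0)
            for f, v in zip(m.feature_ids, vc):
                rows.append((batch, g, f, float(v)))
    if not rows:
        raise ValueError("no (group, batch) cell with >= 2 replicate samples")
    table = pd.DataFrame(rows, columns=["batch", "group", "feature", "vc"])
    return table, float(table["vc"].mean())


def _per_feature_vc(m: IntensityMatrix, b: BatchInfo) -> np.ndarray:
    """Mean replicate VC per feature (over all evaluable group x batch cells)."""
    b = b.align(m.sample_ids)
    cells = group_batch_cells(b.groups, b.batches)
    if not cells:
        raise ValueError("no evaluable replicate cells")
    vcs = np.stack(
        [m.values[idx].std(axis=0, ddof=1) / m.values[idx].mean(axis=0) for idx in cells]
    )
    return vcs.mean(axis=0)


def vc_inflation(
    before: IntensityMatrix,
    after: IntensityMatrix,
    b: BatchInfo,
    threshold: float = 0.05,
) -> float:
    """Fraction of features whose replicate VC increased by >= threshold
    (relative) upon normalization.
    """
    if before.values.shape != after.values.shape or before.feature_ids != after.feature_ids:
        raise ValueError("before/after matrices must share shape and feature ids")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vc_before = _per_feature_vc(before, b)
    vc_after = _per_feature_vc(after, b)
    with np.errstate(invalid="ignore", over="ignore"):
        inflated = (vc_after >= (1.0 + threshold) * vc_before) & (vc_after > vc_before)
    return float(np.mean(inflated))


def batch_mixing(m: IntensityMatrix, b: BatchInfo, seed: int = 0) -> BatchMixing:
    """Cross-validated accuracy of a linear probe predicting batch from
    log10 intensities; chance = majority-batch frequency.  Accuracy close to
    chance means batches are well mixed.
    """
    b = b.align(m.sample_ids)
    y = b.batch_codes()
    counts = np.bincount(y)
    if len(counts) < 2:
        raise ValueError("batch mixing requires >= 2 batches")
    X = StandardScaler().fit_transform(np.log10(m.values))
    n_splits = int(min(5, counts.min()))
    if n_splits < 2:
        raise ValueError("every batch needs >= 2 samples for the probe")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    clf = LogisticRegression(max_iter=1000, random_state=seed)
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return BatchMixing(accuracy=float(scores.mean()), chance=float(counts.max() / counts.sum()))


def spectra_shift(before: IntensityMatrix, after: IntensityMatrix) -> SpectraShift:
    """How much normalization perturbed the mean spectrum: Spearman rank
    correlation of per-feature mean intensities and the largest displacement
    of their z-scores.
    """
    if before.feature_ids != after.feature_ids:
        raise ValueError("before/after matrices must share the feature set")
    mb = before.values.mean(axis=0)
    ma = after.values.mean(axis=0)
    rho = float(stats.spearmanr(mb, ma).statistic) if len(mb) > 1 else 1.0
    zb = stats.zscore(mb) if np.std(mb) > 0 else np.zeros_like(mb)
    za = stats.zscore(ma) if np.std(ma) > 0 else np.zeros_like(ma)
    return SpectraShift(
        rank_correlation=rho, max_z_displacement=float(np.max(np.abs(za - zb)))
    )


def evaluate(
    before: IntensityMatrix,
    after: IntensityMatrix,
    b: BatchInfo,
    seed: int = 0,
    vc_threshold: float = 0.05,
) -> EvaluationReport:
    """Full report for a normalized matrix against its input."""
    within, between = replicate_correlations(after, b)
    _, mean_vc = batch_vc(after, b)
    return EvaluationReport(
        within_batch_corr=_summary(within),
        between_batch_corr=_summary(between),
        mean_batch_vc=mean_vc,
        vc_inflation_fraction=vc_inflation(before, after, b, vc_threshold),
        batch_mixing=batch_mixing(after, b, seed=seed),
        spectra_shift=spectra_shift(before, after),
    )
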