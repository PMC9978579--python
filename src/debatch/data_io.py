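"""Reading, validation and writing of intensity tables and batch information.

File dialects
-------------
* Intensity matrix: CSV/TSV, header row of feature IDs, first column sample
  IDs.  Rows are samples by default; pass ``transpose=True`` for tables with
  features in rows.  Empty cells, ``NA`` and ``NaN`` denote missing values.
* Batch info: CSV/TSV with columns ``sample,batch,group``; an empty ``group``
  marks a non-reference sample.
* Run configuration: a single YAML file; every hyperparameter has a default.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IntensityMatrix",
    "BatchInfo",
    "RunConfig",
    "ValidationReport",
    "ValidationError",
    "ParseError",
    "read_intensities",
    "read_batch_info",
    "apply_min_intensity",
    "validate_inputs",
    "write_normalized",
    "load_config",
]

_MISSING_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


class ValidationError(ValueError):
    """Raised when inputs violate a hard structural requirement."""


class ParseError(ValueError):
    """Raised when a cell cannot be interpreted as a number."""


@dataclass
class IntensityMatrix:
    """Samples x features table of ion intensities.

    Missing cells are encoded as NaN until :func:`apply_min_intensity`
    replaces them; after preprocessing all values are strictly positive.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} names: {sorted(dupes)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            list(self.sample_ids), list(self.feature_ids), self.values.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


@dataclass
class BatchInfo:
    """Per-sample batch label and optional reference-group label.

    ``groups[i] == ""`` marks a non-reference sample.  Batch order (for
    chronology-sensitive operations) is the order of first appearance.
    """

    sample_ids: list[str]
    batches: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.batches = np.asarray(self.batches, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if not (len(self.sample_ids) == len(self.batches) == len(self.groups)):
            raise ValidationError("sample_ids, batches and groups must align")
        dupes = _duplicates(self.sample_ids)
        if dupes:
            raise ValidationError(f"duplicate sample names in batch info: {sorted(dupes)}")

    @property
    def batch_order(self) -> list:
        return list(pd.unique(self.batches))

    def batch_codes(self) -> np.ndarray:
        order = {b: i for i, b in enumerate(self.batch_order)}
        return np.array([order[b] for b in self.batches], dtype=np.intp)

    def reference_groups(self) -> dict:
        """Map group name -> indices of its member samples."""
        out: dict = {}
        for i, g in enumerate(self.groups):
            if g:
                out.setdefault(g, []).append(i)
        return {g: np.asarray(ix, dtype=np.intp) for g, ix in out.items()}

    def align(self, sample_ids: list[str]) -> "BatchInfo":
        """Reorder rows to match ``sample_ids``; error on unknown samples."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples without batch information: {missing}")
        idx = np.array([pos[s] for s in sample_ids], dtype=np.intp)
        return BatchInfo(list(sample_ids), self.batches[idx], self.groups[idx])

    def subset(self, idx: np.ndarray) -> "BatchInfo":
        idx = np.asarray(idx, dtype=np.intp)
        return BatchInfo(
            [self.sample_ids[i] for i in idx], self.batches[idx], self.groups[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.sample_ids, "batch": self.batches, "group": self.groups}
        )


@dataclass
class RunConfig:
    """All knobs of a normalization run, loadable from a single YAML file."""

    data_path: str = ""
    info_path: str = ""
    out_dir: str = "."
    transpose: bool = False
    min_relevant_intensity: float = 1000.0
    variance_ratio: float = 0.9
    latent_dim: int | None = None
    grid_size: int = 50
    lambda_g_range: tuple[float, float] = (1e-3, 10.0)
    lambda_d_range: tuple[float, float] = (1e-3, 10.0)
    lambda_v_range: tuple[float, float] = (1e-3, 10.0)
    lr_range: tuple[float, float] = (1e-4, 1e-2)
    epochs: int = 50
    batch_size: int = 64
    patience: int = 5
    window: int = 5
    collapse_ratio: float = 1e-3
    rg_every: int = 1
    grouping_method: str = "cluster"  # "cluster" | "distance"
    reconstruction_loss: str = "mse"  # "mse" | "mae"
    d_steps_per_g_step: int = 1
    seed: int = 42
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.variance_ratio <= 1.0):
            raise ValidationError("variance_ratio must be in (0, 1]")
        if self.min_relevant_intensity <= 0:
            raise ValidationError("min_relevant_intensity must be > 0")
        if self.grid_size < 1:
            raise ValidationError("grid_size must be >= 1")
        if self.grouping_method not in ("cluster", "distance"):
            raise ValidationError("grouping_method must be 'cluster' or 'distance'")
        if self.reconstruction_loss not in ("mse", "mae"):
            raise ValidationError("reconstruction_loss must be 'mse' or 'mae'")


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("lambda_g_range", "lambda_d_range", "lambda_v_range", "lr_range"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return RunConfig(**raw)


@dataclass
class ValidationReport:
    """Soft issues found in the inputs; hard failures raise instead."""

    samples_missing_batch: list[str] = field(default_factory=list)
    small_batches: list = field(default_factory=list)
    single_batch_groups: list = field(default_factory=list)
    constant_features: list[str] = field(default_factory=list)
    replaced_fraction: float = 0.0
    n_samples: int = 0
    n_features: int = 0

    @property
    def issues(self) -> list[str]:
        out = []
        if self.samples_missing_batch:
            out.append(f"samples without batch label: {self.samples_missing_batch}")
        if self.small_batches:
            out.append(f"batches with fewer than 2 samples: {self.small_batches}")
        if self.single_batch_groups:
            out.append(
                f"reference groups confined to a single batch: {self.single_batch_groups}"
            )
        if self.constant_features:
            out.append(f"constant features after preprocessing: {self.constant_features}")
        return out

    @property
    def passed(self) -> bool:
        return not self.issues


def _read_table(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)


def read_intensities(path: str, transpose: bool = False) -> IntensityMatrix:
    """Read a CSV/TSV intensity table; missing cells become NaN.

    Raises :class:`ParseError` naming the offending row/column for any cell
    that is neither numeric nor a recognized missing-value token.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = _read_table(path)
    if transpose:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    values = np.full(df.shape, np.nan)
    raw = df.to_numpy(dtype=object)
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in _MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(cell)  # exact; avoids fast-path parsers
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {raw[i, j]!r} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                ) from None
    return IntensityMatrix(sample_ids, feature_ids, values)


def read_batch_info(path: str) -> BatchInfo:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample", "batch"):
        if col not in df.columns:
            raise ValidationError(f"batch info file must have a {col!r} column")
    groups = df["group"].str.strip() if "group" in df.columns else [""] * len(df)
    return BatchInfo(
        list(df["sample"].str.strip()),
        df["batch"].str.strip().to_numpy(dtype=object),
        np.asarray(groups, dtype=object),
    )


def apply_min_intensity(
    m: IntensityMatrix, min_relevant_intensity: float = 1000.0
) -> IntensityMatrix:
    """Replace missing and sub-threshold cells with ``min_relevant_intensity``.

    After this call every cell is >= the threshold, hence strictly positive.
    """
    if min_relevant_intensity <= 0:
        raise ValidationError("min_relevant_intensity must be > 0")
    values = m.values.copy()
    mask = np.isnan(values) | (values < min_relevant_intensity)
    values[mask] = min_relevant_intensity
    return IntensityMatrix(list(m.sample_ids), list(m.feature_ids), values)


def validate_inputs(
    m: IntensityMatrix,
    b: BatchInfo,
    min_relevant_intensity: float = 1000.0,
) -> ValidationReport:
    """Check structural requirements of a run; pure (inputs are not mutated).

    Hard failures (raise ValidationError): a sample without batch information,
    or no reference group spanning at least two batches.  Everything else is
    reported as a soft issue.
    """
    info_by_sample = {s: i for i, s in enumerate(b.sample_ids)}
    missing = [s for s in m.sample_ids if s not in info_by_sample]
    if missing:
        raise ValidationError(f"samples without batch information: {missing}")
    aligned = b.align(m.sample_ids)

    report = ValidationReport(n_samples=m.n_samples, n_features=m.n_features)
    batch_counts = pd.Series(aligned.batches).value_counts()
    if len(batch_counts) < 2:
        raise ValidationError("at least 2 distinct batches are required")
    report.small_batches = sorted(batch_counts.index[batch_counts < 2])

    spanning = []
    for g, idx in aligned.reference_groups().items():
        n_batches = len(set(aligned.batches[idx]))
        if n_batches >= 2:
            spanning.append(g)
        else:
            report.single_batch_groups.append(g)
    report.single_batch_groups.sort()
    if not spanning:
        raise ValidationError(
            "no reference group spans at least two batches "
            f"(single-batch groups: {report.single_batch_groups})"
        )

    replaced = np.isnan(m.values) | (m.values < min_relevant_intensity)
    report.replaced_fraction = float(replaced.mean())
    processed = np.where(replaced, min_relevant_intensity, m.values)
    constant = np.ptp(processed, axis=0) == 0
    report.constant_features = [f for f, c in zip(m.feature_ids, constant) if c]
    return report


def write_normalized(m: IntensityMatrix, path: str) -> None:
    """Write a matrix so that ``read_intensities`` round-trips it exactly."""
    m.to_frame().to_csv(path, float_format=None)
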