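import numpy as np
import pytest

from debatch.data_io import BatchInfo, IntensityMatrix, apply_min_intensity
from debatch.synthetic import SimulationDesign, simulate


@pytest.fixture
def toy_matrix() -> IntensityMatrix:
    values = np.array(
        [
            [1e5, 2e5, 3e5],
            [1.1e5, 2.1e5, 3.1e5],
            [0.9e5, 1.9e5, 2.9e5],
            [5e4, 8e4, 1e5],
        ]
    )
    return IntensityMatrix(["s1", "s2", "s3", "s4"], ["f1", "f2", "f3"], values)


@pytest.fixture
def toy_info() -> BatchInfo:
    return BatchInfo(
        ["s1", "s2", "s3", "s4"],
        np.array(["A", "A", "B", "B"], dtype=object),
        np.array(["QC", "QC", "QC", ""], dtype=object),
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small seeded multi-batch dataset shared across tests (read-only)."""
    design = SimulationDesign(
        n_batches=3,
        n_features=30,
        n_nonreference_samples=10,
        batch_log_sd=1.0,
        noise_cv=0.05,
        seed=7,
    )
    m, b, truth = simulate(design)
    return apply_min_intensity(m), b, truth, design
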