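import numpy as np
import pytest

from factorde import simulate
from factorde.types import ExpressionMatrix, SampleDesign


@pytest.fixture
def small_design() -> SampleDesign:
    """Balanced 16-sample single-duration factorial (2 per cell)."""
    return simulate.generate_design(2, durations=(1,)).for_duration(1)


@pytest.fixture
def both_durations_design() -> SampleDesign:
    return simulate.generate_design(2, durations=(1, 5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def noisy_dataset(small_design, rng):
    """16 samples x 30 genes with seeded Gaussian values (no structure)."""
    values = rng.normal(8.0, 1.0, size=(30, small_design.n_samples))
    gene_ids = [f"g{i:03d}" for i in range(30)]
    return ExpressionMatrix(gene_ids, list(small_design.sample_ids), values)
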