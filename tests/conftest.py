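import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from bactoseries import MonthlySeries, SeriesSpec, generate_series


@pytest.fixture
def annual_cosine_series() -> MonthlySeries:
    """Noiseless 10-year series with a single 12-month harmonic."""
    spec = SeriesSpec(
        n_months=120,
        mean=-1.29,
        harmonics=((12.0, 0.04, 2.44),),
        noise_sd=0.0,
        seed=0,
        name="lna_size_like",
    )
    return generate_series(spec)


@pytest.fixture
def white_noise_series() -> MonthlySeries:
    rng = np.random.default_rng(42)
    return MonthlySeries(rng.normal(size=120), name="white")
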