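import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from nmrdyn.context import SpectrometerContext
from nmrdyn.peaklist import PeakList


@pytest.fixture(scope="session")
def ctx() -> SpectrometerContext:
    """Default 800 MHz spectrometer context."""
    return SpectrometerContext()


@pytest.fixture
def base_peaklist() -> PeakList:
    """120-residue synthetic HSQC peak list with reproducible positions."""
    rng = np.random.default_rng(1234)
    n = 120
    residues = np.arange(1, n + 1)
    return PeakList(
        pd.DataFrame(
            {
                "assignment": [f"A{r}N-H" for r in residues],
                "w_N": rng.uniform(105.0, 130.0, n),
                "w_H": rng.uniform(7.0, 9.5, n),
                "height": 1e6 * rng.uniform(0.8, 1.2, n),
            }
        )
    )
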