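from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lipidflux import synthetic
from lipidflux.quantify import AbundanceTable


@pytest.fixture(scope="session")
def small_study():
    """One scaled-down synthetic study shared across tests."""
    return synthetic.generate_study(synthetic.small_design(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_table(values: np.ndarray, lipids: list[str], tissue: str = "liver",
               n_cold: int | None = None) -> AbundanceTable:
    """AbundanceTable helper: columns are mice, first half cold."""
    n = values.shape[1]
    n_cold = n // 2 if n_cold is None else n_cold
    mice = [f"m{i + 1:02d}" for i in range(n)]
    samples = [f"{tissue}_{m}" for m in mice]
    meta = pd.DataFrame(
        {
            "mouse_id": mice,
            "tissue": tissue,
            "temperature": ["cold"] * n_cold + ["room"] * (n - n_cold),
            "amount": 20.0,
        },
        index=samples,
    )
    return AbundanceTable(pd.DataFrame(values, index=lipids, columns=samples), meta)
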