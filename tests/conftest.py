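import numpy as np
import pandas as pd
import pytest

from mirperm.expression_io import ExpressionMatrix
from mirperm.synthetic_data import SimulationConfig, mirna_names


@pytest.fixture()
def toy_matrix() -> ExpressionMatrix:
    """Six probes, 3-vs-3 design, hand-chosen row means (10, 20, 29, 31, 100, 30)."""
    values = pd.DataFrame(
        {
            "FA_1": [10.0, 18.0, 29.0, 31.0, 90.0, 30.0],
            "FA_2": [10.0, 20.0, 29.0, 31.0, 100.0, 30.0],
            "FA_3": [10.0, 22.0, 29.0, 31.0, 110.0, 30.0],
            "CT_1": [10.0, 20.0, 29.0, 31.0, 95.0, 30.0],
            "CT_2": [10.0, 20.0, 29.0, 31.0, 100.0, 30.0],
            "CT_3": [10.0, 20.0, 29.0, 31.0, 105.0, 30.0],
        },
        index=[f"p{i}" for i in range(1, 7)],
    )
    groups = {s: ("treated" if s.startswith("FA") else "control")
              for s in values.columns}
    return ExpressionMatrix(values, groups)


def spiked_config(n_mirnas: int, spikes: dict[str, float], seed: int,
                  **overrides) -> SimulationConfig:
    """Study-ratio config (≈22.5 probes per miRNA), all miRNAs detectable."""
    names = set(mirna_names(n_mirnas))
    unknown = set(spikes) - names
    assert not unknown, unknown
    defaults = dict(
        n_probes=int(round(n_mirnas * 22.5)),
        n_mirnas=n_mirnas,
        detectable_fraction=1.0,
        spiked_mirnas=tuple(spikes.items()),
        noise_sd=0.25,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
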