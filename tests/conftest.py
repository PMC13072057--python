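import numpy as np
import pandas as pd
import pytest

from hemodose import CumulativeDVH, build_reference_model


def toy_table(volumes, flows, names=None, in_field=None):
    """Compartment parameter table from raw fraction lists."""
    k = len(volumes)
    names = names or [f"c{i}" for i in range(k)]
    in_field = in_field if in_field is not None else [True] * k
    return pd.DataFrame({
        "compartment": names,
        "volume_fraction": volumes,
        "flow_fraction": flows,
        "in_field": in_field,
    })


@pytest.fixture
def two_compartment_model():
    """Male totals split 20/80 by volume with equal flows."""
    return build_reference_model(
        "male", toy_table([0.2, 0.8], [0.5, 0.5]), required_compartments=[])


@pytest.fixture
def linear_dvh():
    """Survival dropping linearly from 1 at 0 Gy to 0 at 10 Gy."""
    return CumulativeDVH.from_survival(lambda d: 1 - d / 10.0, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
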