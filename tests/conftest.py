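import numpy as np
import pandas as pd
import pytest

import itvsample as iv


def toy_dataset(values, h_class, position=None, quadrat=None, individual=None,
                trait="y"):
    """Small hand-built dataset; defaults keep all non-varied factors constant."""
    n = len(values)
    df = pd.DataFrame(
        {
            "quadrat": quadrat or ["Q1"] * n,
            "individual": individual or ["I01"] * n,
            "h_class": list(h_class),
            "position": position or ["E"] * n,
            "exposure": ["N"] * n,
            trait: list(values),
        }
    )
    return iv.TraitDataset(df, trait_names=[trait])


@pytest.fixture(scope="session")
def study_dataset():
    """One study-shaped synthetic dataset (3 quadrats of 5/17/12 trees,
    12 leaves each; 408 observations)."""
    return iv.generate_dataset(iv.study_config(), seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact balanced design (10 trees x 8 leaves) for cheap simulations."""
    cfg = iv.SynthConfig(
        individuals_per_quadrat=(3, 4, 3),
        leaves_per_stratum=2,
        traits={
            "sla": iv.TraitModel(8.0, 0.5, {"individual": 0.3, "residual": 0.7}),
            "pi": iv.TraitModel(3.3, 0.4, {"individual": 0.2, "residual": 0.8}),
        },
    )
    return iv.generate_dataset(cfg, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
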