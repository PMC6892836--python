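import numpy as np
import pandas as pd
import pytest

from spectrait import SimulationConfig, SpectraSet, Spectrum, generate_experiment
from spectrait.spectra import GRID


@pytest.fixture(scope="session")
def default_experiment():
    """One realized default trial (384 plots) shared across tests."""
    return generate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def lm_subset(default_experiment):
    """Limited-irrigation plots (192) with aligned traits."""
    exp = default_experiment
    sub = exp.spectra.subset((exp.spectra.meta["treatment"] == "LM").to_numpy())
    traits = exp.traits.set_index("plot_id").loc[sub.plot_ids].reset_index()
    return sub, traits


def random_spectrum(rng: np.random.Generator, plot_id: str = "p1") -> Spectrum:
    return Spectrum(
        plot_id=plot_id,
        genotype="G01",
        treatment="LM",
        year="Y1",
        replicate=1,
        wavelengths=GRID.astype(float),
        reflectance=rng.uniform(0.05, 0.95, size=GRID.size),
    )


def random_spectra_set(rng: np.random.Generator, n: int) -> SpectraSet:
    return SpectraSet.from_spectra(
        [random_spectrum(rng, plot_id=f"p{i}") for i in range(n)]
    )
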