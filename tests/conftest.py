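import warnings

import numpy as np
import pandas as pd
import pytest

from acclimet.containers import SpectrumSet
from acclimet.design import SimulationDesign, default_design
from acclimet.pipeline import PipelineConfig, run_pipeline
from acclimet.synthetic_data import (BackgroundModel, MetaboliteTruth,
                                     NuisanceModel, default_metabolite_truths,
                                     simulate_spectra)


def make_set(ppm, intensities, temperatures=None, sexes=None) -> SpectrumSet:
    """Build a SpectrumSet from raw arrays with minimal metadata."""
    n = np.asarray(intensities).shape[0]
    temperatures = temperatures if temperatures is not None else [20.0] * n
    sexes = sexes if sexes is not None else ["female"] * n
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "sex": sexes,
        "temperature_C": temperatures,
        "replicate": np.arange(n) + 1,
    })
    return SpectrumSet(ppm, intensities, meta)


@pytest.fixture(scope="session")
def design() -> SimulationDesign:
    return default_design()


@pytest.fixture(scope="session")
def clean_truths() -> list[MetaboliteTruth]:
    """Default metabolite panel, for use with nuisance switched off."""
    return default_metabolite_truths()


@pytest.fixture(scope="session")
def noiseless_spectra(design, clean_truths) -> SpectrumSet:
    """Deterministic spectra: no noise, no dilution, no jitter, no
    unassigned background."""
    return simulate_spectra(design, clean_truths, NuisanceModel.none(),
                            seed=0, background=BackgroundModel.none())


@pytest.fixture(scope="session")
def default_bundle():
    """One full default pipeline run, shared by the slower checks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(PipelineConfig(seed=11))
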