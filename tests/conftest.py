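import numpy as np
import pytest

from adhesiokin import (AdhesionDataset, ConditionPreset, NoiseParams,
                        SimConfig, SLSParams, simulate_dataset)


@pytest.fixture
def fibroblast_mild() -> ConditionPreset:
    """Fibroblast kinetics and design with mild observation noise.

    The low-noise regime keeps the kinetic parameters well identified at
    4-5 replicates per time point, which the recovery and oracle checks need.
    """
    return ConditionPreset(
        name="fibroblast_mild",
        sls=SLSParams(F0=15.0, Fmax=300.0, tau=3.7),
        noise=NoiseParams(gamma_mu=0.03, gamma_sigma=1.0),
        baseline_sd=5.0,
        time_points=(0.5, 2.0, 4.0, 6.0, 8.0, 10.0),
    )


@pytest.fixture
def mild_dataset(fibroblast_mild) -> AdhesionDataset:
    return simulate_dataset(fibroblast_mild, SimConfig(seed=11, n_replicates=5))


@pytest.fixture
def noiseless_dataset(fibroblast_mild) -> AdhesionDataset:
    from dataclasses import replace

    quiet = replace(fibroblast_mild, noise=NoiseParams(0.0, 0.0),
                    baseline_sd=0.0)
    return simulate_dataset(quiet, SimConfig(seed=1, n_replicates=5))


@pytest.fixture
def toy_linear_dataset() -> AdhesionDataset:
    """The 3-point hand-example dataset {(1,1),(2,2),(3,3)}."""
    return AdhesionDataset(condition="toy",
                           times=np.array([1.0, 2.0, 3.0]),
                           forces=np.array([1.0, 2.0, 3.0]))
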