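import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fdsvel import (
    CellModel,
    NoiseModel,
    SimulationSpec,
    SolutionConditions,
    SpeciesParams,
    diffusion_from_ff0,
    simulate_scanset,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def conditions():
    return SolutionConditions()


@pytest.fixture(scope="session")
def egfp_cell():
    return CellModel(meniscus=6.0, bottom=7.2, rpm=50000.0)


@pytest.fixture(scope="session")
def tiny_sim(egfp_cell, conditions):
    """A small noise-free single-species run on a 9-point s-grid node."""
    s_grid = np.linspace(1.0, 5.0, 9)
    s_true = float(s_grid[4])
    D = diffusion_from_ff0(s_true * 1e-13, 1.39, conditions)
    spec = SimulationSpec(
        species=[SpeciesParams(s=s_true, D=D, c0=50.0)],
        cell=egfp_cell,
        t_start=600.0,
        t_interval=1500.0,
        n_scans=12,
        dr=0.01,
        gains=(1,),
        noise=NoiseModel(sigma=0.0),
        seed=1,
        n_grid=400,
    )
    return s_grid, s_true, spec, simulate_scanset(spec)
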