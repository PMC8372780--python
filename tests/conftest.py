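import pytest

from bagmf.fitting_selection import FitOptions, FitVector
from bagmf.jw_mapping import map_rates_table
from bagmf.modelfree import ModelFreeParams
from bagmf.synthetic_data import (
    NoiseLevel,
    NoiseModel,
    SyntheticScenario,
    gcn4_like_scenario,
    generate_dataset,
)

TAU_M = 17.5e-9


@pytest.fixture(scope="session")
def options():
    return FitOptions()


@pytest.fixture(scope="session")
def disordered_params():
    """Two-timescale parameters typical of a disordered residue."""
    return ModelFreeParams(TAU_M, 0.754, 0.292, 0.0, 0.838e-9)


@pytest.fixture(scope="session")
def ordered_params():
    return ModelFreeParams(TAU_M, 0.886, 1.0, 0.03e-9, 0.0)


def make_sd_set(params, seed=0, noise_frac=0.015, noe_abs=0.015, residue=1,
                fields=(600.0, 700.0, 800.0, 900.0)):
    """Generate, perturb and map one residue's rates in one step."""
    scenario = SyntheticScenario(
        residues=((residue, params, "test"),),
        fields_MHz=fields,
        noise=NoiseModel(
            R1=NoiseLevel("fractional", noise_frac),
            R2=NoiseLevel("fractional", noise_frac),
            NOE=NoiseLevel("absolute", noe_abs),
        ),
        seed=seed,
    )
    df = generate_dataset(scenario)
    return map_rates_table(df)[0]


@pytest.fixture(scope="session")
def disordered_sd_set(disordered_params):
    return make_sd_set(disordered_params, seed=11)


@pytest.fixture(scope="session")
def disordered_fv(disordered_sd_set):
    return FitVector.from_sd_set(disordered_sd_set)


@pytest.fixture(scope="session")
def gcn4_rates():
    scenario = gcn4_like_scenario(seed=123)
    return scenario, generate_dataset(scenario)
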