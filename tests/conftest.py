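import numpy as np
import pytest

from pepperphys import photosynthesis_models as pm
from pepperphys import synthetic_data as sd

# Default generator calibration per salinity level: light-response
# (alpha, pn_max, kappa, rd) and CO2-response (epsilon, pn_sat, rp).
LIGHT_PARAM_SETS = {
    0.9: pm.LightResponseParams(alpha=0.052, pn_max=19.9, kappa=0.53, rd=2.07),
    4.7: pm.LightResponseParams(alpha=0.047, pn_max=15.7, kappa=0.78, rd=1.78),
    7.0: pm.LightResponseParams(alpha=0.030, pn_max=8.6, kappa=0.83, rd=1.43),
}
CO2_PARAM_SETS = {
    0.9: pm.CO2ResponseParams(epsilon=0.224, pn_sat=61.0, rp=12.7),
    4.7: pm.CO2ResponseParams(epsilon=0.188, pn_sat=55.7, rp=11.2),
    7.0: pm.CO2ResponseParams(epsilon=0.109, pn_sat=42.8, rp=7.5),
}

PPFD_SETPOINTS = np.array(sd.DEFAULT_PPFD_SETPOINTS, dtype=float)
CO2_SETPOINTS = np.array(sd.DEFAULT_CO2_SETPOINTS, dtype=float)


@pytest.fixture(scope="session")
def default_design():
    return sd.ExperimentDesign()


@pytest.fixture(scope="session")
def default_units(default_design):
    return sd.generate_design(default_design)


@pytest.fixture(scope="session")
def noise_free_model(default_design):
    return sd.GenerationModel.default(default_design).noise_free()


@pytest.fixture(scope="session")
def noise_free_tables(default_design, noise_free_model):
    return sd.simulate(default_design, noise_free_model)
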