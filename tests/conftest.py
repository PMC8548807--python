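import warnings

import pytest

from rhabdomsim import model as M
from rhabdomsim import synth as S

warnings.filterwarnings("ignore", message=".*near-saturated.*")


@pytest.fixture(scope="session")
def default_run():
    """Converged fixed-point run of the default red-ommatidium model."""
    cfg = M.default_config()
    f_R, flux, iterations = M.solve_equilibrium_fixed_point(cfg)
    return cfg, f_R, flux, iterations


@pytest.fixture(scope="session")
def nored_run():
    """Converged run of the model without the red screening pigment."""
    cfg = M.default_config(red_pigment=False)
    f_R, flux, iterations = M.solve_equilibrium_fixed_point(cfg)
    return cfg, f_R, flux, iterations


@pytest.fixture(scope="session")
def argynnis_runs():
    """Standard synthetic recording set for one opponent-cell preset."""
    cell = S.make_cell(species="Argynnis paphia")
    protos = S.standard_protocols()
    runs = {
        key: S.generate_run(cell, proto, seed=100 + i)
        for i, (key, proto) in enumerate(protos.items())
    }
    return cell, runs
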