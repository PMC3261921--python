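import numpy as np
import pytest

from ipsense.params import MembraneParams, sodium_template
from ipsense.sensitivity import compute_baseline

# maps and f-I scans run at dt = 0.02 ms (convergence against dt halving is
# itself under test in test_model_core)
MAP_DT = 0.02


@pytest.fixture(scope="session")
def membrane():
    return MembraneParams()


@pytest.fixture(scope="session")
def baseline(membrane):
    """Full gmax = 0 baseline (threshold, inverse gain, AP duration)."""
    return compute_baseline(membrane, None, dt=MAP_DT)


@pytest.fixture(scope="session")
def iaf(membrane):
    from ipsense.iaf_theory import standard_iaf
    return standard_iaf(membrane)


@pytest.fixture(scope="session")
def std_template():
    return sodium_template()  # V_half=-60, k=4, tau=5, p=1, E_X=55


# full-resolution sensitivity estimates for three reference templates,
# shared across the unit suite and the acceptance criteria
@pytest.fixture(scope="session")
def est_std(membrane, baseline, std_template):
    from ipsense.sensitivity import estimate_sensitivities
    return estimate_sensitivities(membrane, std_template, baseline=baseline,
                                  dt=MAP_DT)


@pytest.fixture(scope="session")
def est_mixed(membrane, baseline):
    from ipsense.sensitivity import estimate_sensitivities
    return estimate_sensitivities(membrane, sodium_template(-52.0, 3.0),
                                  baseline=baseline, dt=MAP_DT)


@pytest.fixture(scope="session")
def est_supra(membrane, baseline):
    from ipsense.sensitivity import estimate_sensitivities
    return estimate_sensitivities(membrane, sodium_template(-35.0, 2.0),
                                  baseline=baseline, dt=MAP_DT)


@pytest.fixture(scope="session")
def est_gain(membrane, baseline):
    # gain-dominant template inside the cleanly linear regime
    from ipsense.sensitivity import estimate_sensitivities
    return estimate_sensitivities(membrane, sodium_template(-40.0, 8.0),
                                  baseline=baseline, dt=MAP_DT)
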