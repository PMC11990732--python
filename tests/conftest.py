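import numpy as np
import pytest

from quenchbind import SimConfig, simulate_titration

# Table-of-record constants used across tests: apparent binding constants at
# three temperatures, the fitted thermodynamic pair, and the ternary
# (site-marker) binding constants, all for the serum-albumin/lurasidone system.
KA_BY_T = {298.0: 3.98e6, 303.0: 8.13e6, 308.0: 13.99e6}
DELTA_H = 95.97e3  # J/mol
DELTA_S = 448.58  # J/(mol K)
DELTA_G = {298.0: -37.71e3, 303.0: -39.95e3, 308.0: -42.19e3}  # J/mol
KSV_BY_T = {298.0: 2.51e5, 303.0: 2.43e5, 308.0: 2.30e5}
KA_TERNARY_WF = 3.47e5
KA_TERNARY_IP = 3.55e6

PROTEIN_CONC = 1.6e-6


@pytest.fixture(scope="session")
def static_series():
    """Noise-free 1:1 static titration with a dark complex (known Ka)."""
    series, truth = simulate_titration(SimConfig(Ka_true=1.0e6, seed=1))
    return series, truth


@pytest.fixture(scope="session")
def dynamic_series():
    """Noise-free collisional titration (known Ksv)."""
    series, truth = simulate_titration(
        SimConfig(mechanism="dynamic", Ksv_true=2.51e5, seed=2)
    )
    return series, truth
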