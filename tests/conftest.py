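"""Shared fixtures; the expensive simulations are session-scoped and reused."""

import numpy as np
import pytest

from nigra import analysis
from nigra import simulate as sim
from nigra.cell import Cell, make_cell, validate_tuning
from nigra.channels import CH, N_CHANNELS, load_channel_params
from nigra.surrogate import make_passive_reference_cell


@pytest.fixture(scope="session")
def dls_cell():
    """Reference DLS-projecting cell (fixed seed)."""
    return make_cell("DLS", 1)


@pytest.fixture(scope="session")
def dls_state(dls_cell):
    return sim.settle(dls_cell, duration_ms=4000.0)


@pytest.fixture(scope="session")
def dls_tuning_report(dls_cell):
    return validate_tuning(dls_cell)


@pytest.fixture(scope="session")
def dls_rebound_trace(dls_cell, dls_state):
    """Titrated 2 s step to -80 mV with baseline and post windows."""
    return sim.rebound_protocol(dls_cell, state=dls_state,
                                baseline_ms=3000.0, post_ms=4000.0)


@pytest.fixture(scope="session")
def passive_cell():
    return make_passive_reference_cell(r_MOhm=100.0, c_pF=100.0,
                                       e_rest_mV=-60.0)


def make_toy_cable(n: int = 3) -> Cell:
    """Small active cable for conservation/step oracles (soma-like root plus
    a short chain), with every mechanism present at modest density."""
    cp = load_channel_params()
    area = np.full(n, 2e-5)  # cm^2
    gdens = np.zeros((N_CHANNELS, n))
    for name, dens in (("Na", 2.0), ("KDR", 1.0), ("KA", 0.3), ("HCN", 0.02),
                       ("CaT", 0.2), ("CaL", 0.1), ("CaN", 0.1), ("SK", 0.1),
                       ("M", 0.05), ("ERG", 0.1), ("GIRK", 0.02),
                       ("NaL", 0.004), ("KL", 0.0065)):
        gdens[CH[name]] = dens
    erev = np.zeros(N_CHANNELS)
    rev = cp["reversal_mV"]
    for name, e in (("Na", rev["na"]), ("KDR", rev["k"]), ("KA", rev["k"]),
                    ("HCN", rev["h"]), ("CaT", rev["ca"]), ("CaL", rev["ca"]),
                    ("CaN", rev["ca"]), ("SK", rev["k"]), ("M", rev["k"]),
                    ("ERG", rev["k"]), ("GIRK", rev["k"]), ("NaL", rev["na"]),
                    ("KL", rev["k"])):
        erev[CH[name]] = e
    return Cell(
        n=n,
        parent=np.array([-1] + list(range(n - 1)), dtype=np.int64),
        area_cm2=area,
        g_ax_uS=np.array([0.0] + [5.0] * (n - 1)),
        cm_nF=area * 1e3,
        gdens=gdens,
        erev=erev,
        tau_kv4=40.0,
        f_coupling=0.3,
        tau_micro=10.0,
        channel_params=cp,
    )


@pytest.fixture()
def toy_cable():
    return make_toy_cable()
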