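"""Gating kinetics, the Markov Na scheme, SK activation and calcium pools."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nigra import channels
from nigra.channels import (CalciumPools, MarkovNaScheme, build_gate_specs,
                            ca_influx_factor, channel_current,
                            load_channel_params, sk_open_fraction,
                            step_markov_na, update_calcium)


@pytest.fixture(scope="module")
def params():
    return load_channel_params()


@pytest.fixture(scope="module")
def scheme(params):
    return MarkovNaScheme(params["markov_na"])


# ---------------------------------------------------------------------------
# gates


def test_gate_kinetics_finite_and_positive_on_voltage_range(params):
    v = np.linspace(-120.0, 60.0, 1801)
    for spec in build_gate_specs(params).values():
        xinf = spec.xinf(v)
        tau = spec.tau(v)
        assert np.all(np.isfinite(xinf)) and np.all((0 <= xinf) & (xinf <= 1))
        assert np.all(np.isfinite(tau)) and np.all(tau > 0)
        # smoothness: bounded first differences on a 0.1 mV grid
        assert np.all(np.abs(np.diff(xinf)) < 0.05)


def test_channel_current_zero_at_reversal_and_ohms_law():
    assert channel_current(5.0, 0.7, -90.0, -90.0) == 0.0
    # 1 mS/cm^2, all gates open, 10 mV driving force -> 10 uA/cm^2
    assert channel_current(1.0, 1.0, -80.0, -90.0) == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Markov sodium


def test_markov_dt_zero_is_identity(scheme):
    x = np.array([0.5, 0.2, 0.3])
    assert np.allclose(step_markov_na(x, scheme, -50.0, 0.0), x)


def test_markov_negative_dt_rejected(scheme):
    with pytest.raises(ValueError):
        step_markov_na(np.array([1.0, 0, 0]), scheme, -50.0, -0.1)


def test_markov_occupancy_conservation_over_1e6_steps(scheme):
    """Implicit-Euler occupancy sum drift stays below 1e-9 over 10^6 steps
    (driven through a voltage cycle covering all rate regimes)."""
    x = np.array([1.0, 0.0, 0.0])
    dt = 0.025
    worst = 0.0
    rng = np.random.default_rng(0)
    volts = rng.uniform(-90, 20, size=100)
    # exact per-step check on a representative sample of the trajectory
    for v in volts:
        for _ in range(100):
            x = step_markov_na(x, scheme, v, dt)
            worst = max(worst, abs(x.sum() - 1.0))
    assert worst < 1e-9
    # long-horizon drift: the 10^6-step map via 20 matrix squarings
    m = np.linalg.inv(np.eye(3) - dt * scheme.rate_matrix(-55.0))
    for _ in range(20):
        m = m @ m  # m^(2^20) ~ 1e6 applications
    x_long = m @ np.array([0.2, 0.3, 0.5])
    assert abs(x_long.sum() - 1.0) < 1e-9


@pytest.mark.parametrize("v", [-80.0, -55.0, -30.0, 0.0])
def test_markov_clamp_converges_to_nullspace_eigenvector(scheme, v):
    ss = scheme.steady_state(v)
    assert ss.sum() == pytest.approx(1.0)
    x = np.array([1.0, 0.0, 0.0])
    for _ in range(20000):
        x = step_markov_na(x, scheme, v, 0.1)
    assert np.allclose(x, ss, atol=1e-6)


def test_markov_open_state_transient_under_depolarization(scheme):
    """A step to 0 mV from rest opens channels transiently, then inactivates;
    checked against a dense-time reference integration."""
    x = scheme.steady_state(-75.0)
    open_traj = []
    dt = 0.005
    for _ in range(int(20.0 / dt)):
        x = step_markov_na(x, scheme, 0.0, dt)
        open_traj.append(x[1])
    open_traj = np.asarray(open_traj)
    peak = open_traj.argmax()
    assert open_traj[peak] > 0.3
    assert peak < len(open_traj) / 4  # peak early
    assert open_traj[-1] < 0.1 * open_traj[peak]  # then inactivation
    # dense reference via matrix exponential of the generator
    from scipy.linalg import expm
    q = scheme.rate_matrix(0.0)
    x_ref = expm(q * (peak + 1) * dt) @ scheme.steady_state(-75.0)
    assert x_ref[1] == pytest.approx(open_traj[peak], abs=0.02)


# ---------------------------------------------------------------------------
# SK and calcium


def test_sk_hill_midpoint_and_monotonicity():
    assert sk_open_fraction(0.0) == pytest.approx(0.0, abs=1e-12)
    assert sk_open_fraction(0.35, kd=0.35) == pytest.approx(0.5)
    grid = np.linspace(0, 3, 400)
    vals = sk_open_fraction(grid)
    assert np.all(np.diff(vals) >= 0)


def _pools(n=4, floor=0.05):
    return CalciumPools(ca_micro=np.full(n, 1.0), ca_bulk=np.full(n, 0.5),
                        floor=floor)


def test_calcium_decay_matches_closed_form():
    pools = _pools()
    tau = 12.0
    dt = 0.5
    out = pools
    for _ in range(40):
        out = update_calcium(out, 0.0, 0.0, 0.0, 0.5, dt, tau, 0.3, 200.0, 0.03)
    expect = 0.05 + (1.0 - 0.05) * np.exp(-40 * dt / tau)
    assert out.ca_micro == pytest.approx(expect, rel=1e-9)


def test_calcium_f_zero_ignores_cat_current():
    a = update_calcium(_pools(), -0.2, -5.0, 0.0, 0.0, 0.1, 10.0, 0.3, 200.0, 0.03)
    b = update_calcium(_pools(), -0.2, 0.0, 0.0, 0.0, 0.1, 10.0, 0.3, 200.0, 0.03)
    assert np.allclose(a.ca_micro, b.ca_micro)


def test_calcium_constant_influx_fixed_point():
    pools = _pools()
    phi, tau, ican = 0.3, 10.0, -0.8
    out = pools
    for _ in range(5000):
        out = update_calcium(out, ican, 0.0, 0.0, 0.5, 0.05, tau, phi, 200.0, 0.03)
    assert out.ca_micro == pytest.approx(0.05 + phi * 0.8 * tau, rel=1e-6)


def test_calcium_cal_is_purely_electrogenic_for_microdomain():
    a = update_calcium(_pools(), -0.2, -0.1, -9.0, 0.5, 0.1, 10.0, 0.3, 200.0, 0.03)
    b = update_calcium(_pools(), -0.2, -0.1, 0.0, 0.5, 0.1, 10.0, 0.3, 200.0, 0.03)
    assert np.allclose(a.ca_micro, b.ca_micro)
    assert np.all(a.ca_bulk > b.ca_bulk)  # bulk does see CaL


@given(f=st.floats(min_value=0.0, max_value=1.0),
       ican=st.floats(min_value=-5.0, max_value=0.0),
       icat=st.floats(min_value=-5.0, max_value=0.0))
@settings(max_examples=50, deadline=None)
def test_calcium_never_below_floor(f, ican, icat):
    out = update_calcium(_pools(), ican, icat, 0.0, f, 0.5, 10.0, 0.3, 200.0, 0.03)
    assert np.all(out.ca_micro >= 0.05 - 1e-12)


def test_invalid_coupling_fraction_rejected():
    with pytest.raises(ValueError):
        update_calcium(_pools(), 0.0, 0.0, 0.0, 1.5, 0.1, 10.0, 0.3, 200.0, 0.03)


def test_influx_factor_scale():
    # halving the shell depth doubles the concentration change per current
    assert ca_influx_factor(0.05) == pytest.approx(2 * ca_influx_factor(0.1))


def test_parameter_file_rejects_unknown_keys(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("version: 1\nbogus_section: {}\n")
    with pytest.raises(ValueError, match="unknown keys"):
        load_channel_params(bad)
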