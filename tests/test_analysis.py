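"""Metric extraction: filtering, spike detection, rebound/sag/Rin metrics,
burst segmentation and the series-resistance arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nigra import analysis
from nigra.analysis import (ElectrodeCircuit, baseline_stats,
                            detect_spikes_in_vitro, detect_spikes_in_vivo,
                            input_resistance, lowpass_1khz, r_isi_frequencies,
                            rebound_delay, sag_amplitude, segment_bursts,
                            series_resistance_error)
from nigra.simulate import SimulationConfig, StimulusProtocol, VoltageTrace, integrate
from nigra.surrogate import SurrogateSpec, make_surrogate_trace


def _sine_trace(freq_hz, amp=5.0, khz=20.0, dur_ms=1000.0):
    t = np.arange(0, dur_ms, 1.0 / khz)
    v = -60.0 + amp * np.sin(2 * np.pi * freq_hz * t / 1e3)
    return VoltageTrace(times_ms=t, v_mV=v[:, None], sites=(0,),
                        sample_interval_ms=1.0 / khz)


# ---------------------------------------------------------------------------
# filter


def test_lowpass_dc_gain_unity():
    t = np.arange(0, 500, 0.05)
    tr = VoltageTrace(times_ms=t, v_mV=np.full((len(t), 1), -55.0),
                      sites=(0,), sample_interval_ms=0.05)
    out = lowpass_1khz(tr)
    assert np.allclose(out.soma, -55.0, atol=1e-9)


@pytest.mark.parametrize("freq,cond", [(100.0, "pass"), (5000.0, "stop")])
def test_lowpass_frequency_response(freq, cond):
    tr = _sine_trace(freq)
    out = lowpass_1khz(tr)
    mid = slice(2000, -2000)  # avoid edge effects
    gain = (out.soma[mid].max() - out.soma[mid].min()) / 10.0
    if cond == "pass":
        assert gain > 0.99
    else:
        assert gain < 0.10


def test_lowpass_rejects_undersampled():
    with pytest.raises(ValueError):
        lowpass_1khz(_sine_trace(100.0, khz=1.5))


# ---------------------------------------------------------------------------
# spike detection


def test_in_vitro_detector_recovers_planted_spikes():
    times = tuple(np.arange(500.0, 5500.0, 500.0))  # 10 spikes
    spec = SurrogateSpec(duration_ms=6000.0, spike_times_ms=times)
    tr, truth = make_surrogate_trace(spec)
    spikes = detect_spikes_in_vitro(tr)
    assert len(spikes) == 10
    assert np.max(np.abs(spikes.times_ms - truth["spike_times_ms"])) \
        <= tr.sample_interval_ms + 1e-9


def test_in_vitro_detector_flat_and_slow_ramp_empty():
    t = np.arange(0, 1000, 0.05)
    flat = VoltageTrace(times_ms=t, v_mV=np.full((len(t), 1), -60.0),
                        sites=(0,), sample_interval_ms=0.05)
    assert len(detect_spikes_in_vitro(flat)) == 0
    # 5 mV/ms ramp never meets the 10 mV/ms criterion
    ramp = VoltageTrace(times_ms=t, v_mV=(-80 + 5.0 * np.minimum(t, 20))[:, None],
                        sites=(0,), sample_interval_ms=0.05)
    assert len(detect_spikes_in_vitro(ramp, filter_first=False)) == 0


def test_in_vivo_detector_recovers_planted_spikes_in_noise():
    times = tuple(np.arange(400.0, 7400.0, 700.0))
    spec = SurrogateSpec(duration_ms=8000.0, spike_times_ms=times,
                         noise_sd_mV=1.0, seed=4)
    tr, truth = make_surrogate_trace(spec)
    spikes = detect_spikes_in_vivo(tr)
    assert len(spikes) == len(truth["spike_times_ms"])
    assert np.max(np.abs(spikes.times_ms - truth["spike_times_ms"])) <= 0.5


def test_in_vivo_detector_rejects_subthreshold_transient():
    """A fast blip satisfying the dV/dt criterion but staying within 10 mV
    of the trace mean is rejected by the three-condition rule."""
    t = np.arange(0, 2000, 0.05)
    v = np.full(len(t), -60.0)
    i0 = 20000
    v[i0:i0 + 40] += np.linspace(0, 6, 40)       # 3 mV/ms rise to -54
    v[i0 + 40:i0 + 80] += np.linspace(6, 0, 40)
    v[i0:i0 + 10] += np.linspace(0, 1.2, 10)     # brief >10 mV/ms segment
    tr = VoltageTrace(times_ms=t, v_mV=v[:, None], sites=(0,),
                      sample_interval_ms=0.05)
    assert len(detect_spikes_in_vivo(tr, filter_first=False)) == 0


# ---------------------------------------------------------------------------
# rebound metrics


@pytest.fixture(scope="module")
def rebound_surrogate():
    proto = StimulusProtocol(amplitude_pA=-100.0, onset_ms=2000.0,
                             duration_ms=2000.0)
    spec = SurrogateSpec(
        duration_ms=9000.0, baseline_mV=-55.0,
        spike_times_ms=(300.0, 800.0, 1300.0, 1800.0),
        step=proto, vmin_mV=-80.0, sag_mV=10.0,
        rebound_delay_ms=86.0, rebound_isis_ms=(150.0, 200.0, 250.0,
                                                300.0, 350.0, 400.0))
    return make_surrogate_trace(spec)


def test_rebound_delay_from_planted_truth(rebound_surrogate):
    tr, truth = rebound_surrogate
    spikes = detect_spikes_in_vitro(tr)
    assert rebound_delay(spikes, tr.protocol) == pytest.approx(0.086, abs=1e-3)


def test_rebound_delay_none_when_no_spike():
    proto = StimulusProtocol(amplitude_pA=-50.0, onset_ms=100.0,
                             duration_ms=200.0)
    spec = SurrogateSpec(duration_ms=1000.0, step=proto, vmin_mV=-80.0)
    tr, _ = make_surrogate_trace(spec)
    spikes = detect_spikes_in_vitro(tr)
    assert rebound_delay(spikes, proto) is None


def test_r_isi_frequencies_oracle(rebound_surrogate):
    tr, truth = rebound_surrogate
    spikes = detect_spikes_in_vitro(tr)
    freqs, complete = r_isi_frequencies(spikes, tr.protocol)
    assert complete
    expect = 1e3 / np.asarray(truth["rebound_isis_ms"])
    assert np.allclose(freqs, expect, rtol=0.02)
    # consistency: first r-ISI start = offset + rebound delay
    post = spikes.after(tr.protocol.offset_ms)
    delay = rebound_delay(spikes, tr.protocol)
    assert post.times_ms[0] == pytest.approx(
        tr.protocol.offset_ms + delay * 1e3, abs=tr.sample_interval_ms)


def test_r_isi_uniform_100ms_gives_10hz():
    proto = StimulusProtocol(amplitude_pA=-50.0, onset_ms=100.0,
                             duration_ms=100.0)
    spec = SurrogateSpec(duration_ms=2000.0, step=proto, vmin_mV=-80.0,
                         rebound_delay_ms=50.0,
                         rebound_isis_ms=(100.0,) * 6)
    tr, _ = make_surrogate_trace(spec)
    freqs, complete = r_isi_frequencies(detect_spikes_in_vitro(tr), proto)
    assert complete
    assert np.allclose(freqs, 10.0, rtol=0.01)


def test_r_isi_too_few_spikes_flagged():
    spikes = detect_spikes_in_vitro(
        make_surrogate_trace(SurrogateSpec(duration_ms=500.0))[0])
    proto = StimulusProtocol(amplitude_pA=-50.0, onset_ms=10.0, duration_ms=10.0)
    freqs, complete = r_isi_frequencies(spikes, proto)
    assert freqs == [] and not complete


def test_sag_planted_10mV(rebound_surrogate):
    tr, truth = rebound_surrogate
    assert sag_amplitude(tr) == pytest.approx(10.0, abs=0.2)


def test_sag_passive_response_is_zero():
    proto = StimulusProtocol(amplitude_pA=-100.0, onset_ms=500.0,
                             duration_ms=2000.0)
    spec = SurrogateSpec(duration_ms=3000.0, step=proto, vmin_mV=-80.0,
                         sag_mV=0.0)
    tr, _ = make_surrogate_trace(spec)
    assert sag_amplitude(tr) == pytest.approx(0.0, abs=0.1)


def test_input_resistance_recovers_known_r(passive_cell):
    traces = []
    for amp in (-50.0, -100.0, -150.0):
        proto = StimulusProtocol(amplitude_pA=amp, onset_ms=50.0,
                                 duration_ms=300.0)
        traces.append(integrate(passive_cell, proto,
                                SimulationConfig(duration_ms=400.0)))
    pm = input_resistance(traces)
    assert pm.input_resistance_MOhm == pytest.approx(100.0, rel=0.01)


def test_input_resistance_needs_two_levels(passive_cell):
    proto = StimulusProtocol(amplitude_pA=-50.0, onset_ms=50.0,
                             duration_ms=200.0)
    tr = integrate(passive_cell, proto, SimulationConfig(duration_ms=300.0))
    with pytest.raises(ValueError):
        input_resistance([tr, tr])


# ---------------------------------------------------------------------------
# bursts and baseline


def _brute_force_bursts(times):
    """Literal re-implementation of the two-threshold rule (oracle)."""
    bursts, cur = [], []
    for i in range(1, len(times)):
        isi = times[i] - times[i - 1]
        if not cur and isi < 80.0:
            cur = [i - 1, i]
        elif cur and isi > 160.0:
            bursts.append(cur)
            cur = []
        elif cur:
            cur.append(i)
    if cur:
        bursts.append(cur)
    return bursts


def test_burst_rule_on_worked_example():
    times = np.array([0.0, 70.0, 140.0, 340.0])  # ISIs 70, 70, 200
    assert segment_bursts(times) == [[0, 1, 2]]


def test_single_spike_no_burst():
    assert segment_bursts(np.array([100.0])) == []


def test_burst_segmentation_equals_oracle_on_random_trains():
    rng = np.random.default_rng(12345)
    for _ in range(10_000):
        n = rng.integers(0, 12)
        times = np.cumsum(rng.uniform(5.0, 300.0, size=n))
        assert segment_bursts(times) == _brute_force_bursts(times)


def test_baseline_stats_regular_and_poisson():
    regular = np.arange(0.0, 10_000.0, 200.0)
    rate, cv = baseline_stats(regular, (0.0, 10_000.0))
    assert rate == pytest.approx(5.0)
    assert cv == pytest.approx(0.0, abs=1e-12)
    from nigra.surrogate import make_poisson_train
    train = make_poisson_train(5.0, 1_000_000.0, seed=2)
    _, cv = baseline_stats(train, (0.0, 1_000_000.0))
    assert cv == pytest.approx(1.0, abs=0.05)


# ---------------------------------------------------------------------------
# offsets and electrode arithmetic


def test_metrics_dc_offset_invariance(rebound_surrogate):
    tr, _ = rebound_surrogate
    shifted = VoltageTrace(times_ms=tr.times_ms, v_mV=tr.v_mV + 7.0,
                           sites=tr.sites,
                           sample_interval_ms=tr.sample_interval_ms,
                           protocol=tr.protocol)
    s0 = detect_spikes_in_vitro(tr)
    s1 = detect_spikes_in_vitro(shifted)
    assert np.allclose(s0.times_ms, s1.times_ms)
    assert rebound_delay(s0, tr.protocol) == rebound_delay(s1, tr.protocol)
    assert sag_amplitude(shifted) == pytest.approx(sag_amplitude(tr), abs=1e-9)
    # absolute-voltage metrics shift by exactly the offset
    assert analysis.vmin_during_step(shifted) == pytest.approx(
        analysis.vmin_during_step(tr) + 7.0)


@pytest.mark.parametrize("rs,rm,expect,tol", [
    (10.0, 1000.0, 1.0, 0.02),    # in-vitro electrode: ~1% error
    (30.0, 300.0, 9.09, 0.01),    # in-vivo electrode: ~10% error
    (50.0, 50.0, 50.0, 1e-9),     # symmetric case: exactly half
])
def test_series_resistance_voltage_divider(rs, rm, expect, tol):
    assert series_resistance_error(ElectrodeCircuit(rs, rm)) == \
        pytest.approx(expect, rel=max(tol, 1e-9), abs=0.02)


def test_electrode_circuit_requires_positive_resistances():
    with pytest.raises(ValueError):
        ElectrodeCircuit(-1.0, 100.0)


@given(st.floats(min_value=0.1, max_value=1e4),
       st.floats(min_value=0.1, max_value=1e4))
@settings(max_examples=50, deadline=None)
def test_series_resistance_error_bounded(rs, rm):
    err = series_resistance_error(ElectrodeCircuit(rs, rm))
    assert 0.0 < err < 100.0
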