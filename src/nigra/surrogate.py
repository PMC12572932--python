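"""Surrogate current-clamp traces and spike trains with known ground truth.

Emulates the statistical structure the analysis pipeline assumes — 20 kHz
sampling, stereotyped action potentials with known peak times, a
hyperpolarizing step with a known minimum and a double-exponential sag, a
scheduled rebound burst, and Gaussian noise — without any biophysics, so the
metric extractors can be tested against planted truth.  Deliberately
independent of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from nigra.simulate import StimulusProtocol, VoltageTrace


@dataclass
class SurrogateSpec:
    """Construction plan for one surrogate trace; all times in ms."""

    sampling_khz: float = 20.0
    duration_ms: float = 8000.0
    baseline_mV: float = -55.0
    # AP template
    ap_threshold_mV: float = -40.0
    ap_peak_mV: float = 20.0
    ap_width_ms: float = 2.0
    ap_ahp_mV: float = -65.0
    spike_times_ms: tuple[float, ...] = ()
    # hyperpolarizing step
    step: Optional[StimulusProtocol] = None
    vmin_mV: float = -80.0
    sag_mV: float = 0.0
    sag_tau_ms: float = 200.0
    step_tau_ms: float = 40.0
    # rebound schedule: first peak at offset + delay, then ISIs
    rebound_delay_ms: Optional[float] = None
    rebound_isis_ms: tuple[float, ...] = ()
    noise_sd_mV: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_mV < 0:
            raise ValueError("noise SD must be >= 0")
        if self.vmin_mV < -120:
            raise ValueError("Vmin below -120 mV is outside the valid range")
        if list(self.spike_times_ms) != sorted(self.spike_times_ms):
            raise ValueError("planted spike times must be sorted")

    def all_spike_times(self) -> np.ndarray:
        times = list(self.spike_times_ms)
        if self.step is not None and self.rebound_delay_ms is not None:
            t = self.step.offset_ms + self.rebound_delay_ms
            times.append(t)
            for isi in self.rebound_isis_ms:
                t += isi
                times.append(t)
        return np.asarray(sorted(times))


def _ap_template(spec: SurrogateSpec, dt: float) -> tuple[np.ndarray, int]:
    """Stereotyped spike: cosine-bump rise/fall above threshold with the
    requested width at threshold, plus a brief afterhyperpolarization.
    Returns (waveform relative to baseline, index of the peak sample)."""
    w = spec.ap_width_ms
    rise = 0.45 * w
    fall = w - rise
    ahp_dur = 3.0 * w
    t_pre = np.arange(-2.0 * rise, -rise, dt)
    t_rise = np.arange(-rise, 0, dt)
    t_fall = np.arange(0, fall, dt)
    t_ahp = np.arange(fall, fall + ahp_dur, dt)
    base = spec.baseline_mV
    thr = spec.ap_threshold_mV
    pk = spec.ap_peak_mV
    ahp = spec.ap_ahp_mV
    # fast approach from baseline to threshold, ensures a steep upstroke
    pre = base + (thr - base) * (1 + (t_pre + rise) / rise)
    pre = np.clip(pre, min(base, thr), max(base, thr))
    up = thr + (pk - thr) * np.sin(np.pi / 2 * (t_rise + rise) / rise) ** 2
    down = pk + (ahp - pk) * np.sin(np.pi / 2 * t_fall / fall) ** 2
    rec = ahp + (base - ahp) * (t_ahp - fall) / ahp_dur
    wave = np.concatenate([pre, up, down, rec]) - base
    peak_idx = len(t_pre) + len(t_rise)
    return wave, peak_idx


def make_surrogate_trace(spec: SurrogateSpec) -> tuple[VoltageTrace, dict]:
    """Deterministic surrogate trace plus its ground-truth record.

    At zero noise the planted spike peaks land on the requested times (to one
    sample), the in-step minimum equals vmin and the sag equals the spec sag
    within discretization error.
    """
    dt = 1.0 / spec.sampling_khz
    n = int(round(spec.duration_ms / dt))
    t = np.arange(n) * dt
    v = np.full(n, spec.baseline_mV)

    if spec.step is not None:
        p = spec.step
        inside = (t >= p.onset_ms) & (t < p.offset_ms)
        ts = t[inside] - p.onset_ms
        depth = spec.vmin_mV - spec.baseline_mV
        # RC-like drop scaled to touch vmin exactly at t_min, then a sag
        # relaxation from vmin toward vmin + sag
        t_min = 3.0 * spec.step_tau_ms
        scale = 1.0 - np.exp(-t_min / spec.step_tau_ms)
        drop = depth * np.minimum(
            (1 - np.exp(-ts / spec.step_tau_ms)) / scale, 1.0)
        sag = spec.sag_mV * (1 - np.exp(-np.maximum(ts - t_min, 0.0)
                                        / spec.sag_tau_ms))
        v[inside] = spec.baseline_mV + drop + sag
        after = t >= p.offset_ms
        v_end = v[inside][-1] if inside.any() else spec.baseline_mV
        v[after] = spec.baseline_mV + (v_end - spec.baseline_mV) * np.exp(
            -(t[after] - p.offset_ms) / spec.step_tau_ms)

    wave, peak_idx = _ap_template(spec, dt)
    truth_times = []
    last_end = -np.inf
    for st in spec.all_spike_times():
        i_pk = int(round(st / dt))
        i0 = i_pk - peak_idx
        i1 = i0 + len(wave)
        if i0 < 0 or i1 > n:
            continue
        if i0 < last_end:
            raise ValueError(f"AP templates overlap near t = {st:.1f} ms")
        v[i0:i1] = v[i0:i1] + wave
        truth_times.append(i_pk * dt)
        last_end = i1

    if spec.noise_sd_mV > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd_mV, size=n)

    trace = VoltageTrace(times_ms=t, v_mV=v[:, None], sites=(0,),
                         sample_interval_ms=dt, protocol=spec.step)
    truth = {
        "spike_times_ms": np.asarray(truth_times),
        "vmin_mV": spec.vmin_mV,
        "sag_mV": spec.sag_mV,
        "rebound_delay_s": (None if spec.rebound_delay_ms is None
                            else spec.rebound_delay_ms / 1e3),
        "rebound_isis_ms": np.asarray(spec.rebound_isis_ms),
    }
    return trace, truth


def make_poisson_train(rate_hz: float, duration_ms: float,
                       seed: int = 0) -> np.ndarray:
    """Homogeneous Poisson spike times (ms), deterministic per seed."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if rate_hz == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n_expect = rate_hz * duration_ms / 1e3
    n = rng.poisson(n_expect)
    return np.sort(rng.uniform(0.0, duration_ms, size=n))


def make_passive_reference_cell(r_MOhm: float = 100.0, c_pF: float = 100.0,
                                e_rest_mV: float = -60.0):
    """Single-compartment leak-only cell with analytic R and C.

    Its step response is V(t) = E + I*R*(1 - exp(-t/RC)), the closed-form
    oracle for the integrator, input-resistance and titration tests.
    """
    from nigra.cell import Cell
    from nigra.channels import CH, N_CHANNELS, load_channel_params

    cp = load_channel_params()
    area = 1e-4  # cm^2; densities below scale R and C onto this area
    g_uS = 1.0 / r_MOhm  # total leak in uS
    gdens = np.zeros((N_CHANNELS, 1))
    gdens[CH["KL"], 0] = g_uS / (area * 1e3)  # mS/cm^2
    erev = np.zeros(N_CHANNELS)
    erev[CH["KL"]] = e_rest_mV
    return Cell(
        n=1,
        parent=np.array([-1], dtype=np.int64),
        area_cm2=np.array([area]),
        g_ax_uS=np.zeros(1),
        cm_nF=np.array([c_pF * 1e-3]),
        gdens=gdens,
        erev=erev,
        tau_kv4=50.0,
        f_coupling=0.0,
        tau_micro=10.0,
        channel_params=cp,
    )
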