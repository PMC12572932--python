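"""Current-clamp electrophysiology metrics for simulated and recorded traces.

Implements the standard pipeline: zero-phase 1 kHz low-pass, derivative-based
spike detection (10 mV/ms criterion in vitro; a three-condition rule within a
3 ms window in vivo), rebound delay and rebound ISI frequencies, sag
amplitude, input resistance from the V-I slope, two-threshold burst
segmentation (<80 ms onset / >160 ms termination), baseline rate and CV, and
the series-resistance voltage-divider error.

Metrics that are undefined on a given trace are flagged (None / empty with a
flag), never encoded as sentinel numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from nigra.simulate import StimulusProtocol, VoltageTrace

DVDT_THRESHOLD = 10.0  # mV/ms upstroke criterion
IN_VIVO_WINDOW_MS = 3.0
IN_VIVO_MIN_DOWNSTROKE = -5.0  # mV/ms
IN_VIVO_PEAK_ABOVE_MEAN = 10.0  # mV
BURST_ONSET_ISI_MS = 80.0
BURST_END_ISI_MS = 160.0
REBOUND_HORIZON_MS = 5000.0


@dataclass
class SpikeTrain:
    """Detected spikes with per-spike threshold and peak voltages."""

    times_ms: np.ndarray         # peak times, strictly increasing
    thresholds_mV: np.ndarray
    peaks_mV: np.ndarray
    threshold_times_ms: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times_ms) > 1 and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_ms)

    @classmethod
    def empty(cls) -> "SpikeTrain":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), z.copy())

    def after(self, t_ms: float) -> "SpikeTrain":
        m = self.times_ms > t_ms
        return SpikeTrain(self.times_ms[m], self.thresholds_mV[m],
                          self.peaks_mV[m], self.threshold_times_ms[m])


@dataclass
class ReboundMetrics:
    """Per-trial derived quantities for the hyperpolarizing-step protocol."""

    vmin_mV: float
    rebound_delay_s: Optional[float]
    r_isi_freq_hz: list[float]
    r_isi_complete: bool
    sag_mV: float
    baseline_rate_hz: float
    baseline_cv: float

    def to_dict(self) -> dict:
        d = {
            "vmin_mV": self.vmin_mV,
            "rebound_delay_s": self.rebound_delay_s,
            "sag_mV": self.sag_mV,
            "baseline_rate_hz": self.baseline_rate_hz,
            "baseline_cv": self.baseline_cv,
            "r_isi_complete": self.r_isi_complete,
        }
        for i in range(6):
            d[f"r_isi_freq_{i + 1}_hz"] = (
                self.r_isi_freq_hz[i] if i < len(self.r_isi_freq_hz) else None
            )
        return d


@dataclass(frozen=True)
class ElectrodeCircuit:
    """Series (electrode) and membrane resistance of the recording circuit."""

    rs_MOhm: float
    rm_MOhm: float

    def __post_init__(self) -> None:
        if self.rs_MOhm <= 0 or self.rm_MOhm <= 0:
            raise ValueError("resistances must be positive")


@dataclass
class PassiveMetrics:
    input_resistance_MOhm: float
    vi_pairs: list[tuple[float, float]]  # (delta_I_pA, delta_V_mV)


# ---------------------------------------------------------------------------
# filtering and spike detection


def lowpass_1khz(trace: VoltageTrace, cutoff_hz: float = 1000.0) -> VoltageTrace:
    """Zero-phase Butterworth low-pass at 1 kHz (DC gain 1)."""
    fs = trace.sampling_rate_khz * 1e3
    if fs < 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {fs:.0f} Hz below Nyquist for {cutoff_hz:.0f} Hz cutoff"
        )
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    v = signal.sosfiltfilt(sos, trace.v_mV, axis=0)
    return VoltageTrace(times_ms=trace.times_ms, v_mV=v, sites=trace.sites,
                        sample_interval_ms=trace.sample_interval_ms,
                        protocol=trace.protocol, currents_nA=trace.currents_nA)


def _derivative(v: np.ndarray, dt_ms: float) -> np.ndarray:
    """Central-difference dV/dt in mV/ms."""
    return np.gradient(v, dt_ms)


def _upstroke_spikes(t: np.ndarray, v: np.ndarray, dvdt: np.ndarray):
    """Shared scan: one spike per suprathreshold excursion.

    The threshold sample is the first of each upstroke where dV/dt >= 10
    mV/ms; the peak is the local maximum that follows; the detector is then
    refractory until V falls back below that spike's threshold voltage.
    """
    thr_t, thr_v, pk_t, pk_v = [], [], [], []
    n = len(v)
    i = 1
    while i < n:
        if dvdt[i] >= DVDT_THRESHOLD and dvdt[i - 1] < DVDT_THRESHOLD:
            v_thr = v[i]
            # walk to the local maximum (allow brief dips during the upstroke)
            j = i
            while j + 1 < n and v[j + 1] >= v[j]:
                j += 1
            thr_t.append(t[i])
            thr_v.append(v_thr)
            pk_t.append(t[j])
            pk_v.append(v[j])
            # refractory until V < threshold voltage again
            k = j
            while k < n and v[k] >= v_thr:
                k += 1
            i = max(k, j + 1)
        else:
            i += 1
    return (np.asarray(pk_t), np.asarray(thr_v), np.asarray(pk_v),
            np.asarray(thr_t))


def detect_spikes_in_vitro(trace: VoltageTrace, column: int = 0,
                           filter_first: bool = True) -> SpikeTrain:
    """Spike detection by the dV/dt >= 10 mV/ms upstroke criterion."""
    tr = lowpass_1khz(trace) if filter_first else trace
    v = tr.v_mV[:, column]
    dvdt = _derivative(v, tr.sample_interval_ms)
    return SpikeTrain(*_upstroke_spikes(tr.times_ms, v, dvdt))


def detect_spikes_in_vivo(trace: VoltageTrace, column: int = 0,
                          filter_first: bool = True) -> SpikeTrain:
    """Three-condition spike detection for noisy (in-vivo-like) traces.

    A candidate upstroke is accepted only if, within a 3 ms window around it:
    dV/dt reaches >= 10 mV/ms, the minimum dV/dt is < -5 mV/ms, and the
    voltage maximum exceeds the whole-trace mean by > 10 mV.
    """
    tr = lowpass_1khz(trace) if filter_first else trace
    t = tr.times_ms
    v = tr.v_mV[:, column]
    dt = tr.sample_interval_ms
    dvdt = _derivative(v, dt)
    v_mean = float(v.mean())
    cand = _upstroke_spikes(t, v, dvdt)
    half = int(round(IN_VIVO_WINDOW_MS / dt))
    keep = []
    for k, tt in enumerate(cand[3]):  # threshold times
        i0 = int(np.searchsorted(t, tt))
        lo, hi = max(0, i0), min(len(v), i0 + half + 1)
        win_dv = dvdt[lo:hi]
        win_v = v[lo:hi]
        if (win_dv.max(initial=-np.inf) >= DVDT_THRESHOLD
                and win_dv.min(initial=np.inf) < IN_VIVO_MIN_DOWNSTROKE
                and win_v.max(initial=-np.inf) > v_mean + IN_VIVO_PEAK_ABOVE_MEAN):
            keep.append(k)
    keep = np.asarray(keep, dtype=int)
    return SpikeTrain(cand[0][keep], cand[1][keep], cand[2][keep], cand[3][keep])


def spike_widths_at_threshold(trace: VoltageTrace, spikes: SpikeTrain,
                              column: int = 0) -> np.ndarray:
    """AP width: time between up and down crossings of each spike's threshold
    voltage (interpolated between samples)."""
    t = trace.times_ms
    v = trace.v_mV[:, column]
    widths = []
    for tt, vt in zip(spikes.threshold_times_ms, spikes.thresholds_mV):
        i0 = int(np.searchsorted(t, tt))
        j = i0
        while j + 1 < len(v) and v[j + 1] >= vt:
            j += 1
        if j + 1 >= len(v):
            widths.append(np.nan)
            continue
        # linear interpolation of the downward crossing
        frac = (v[j] - vt) / (v[j] - v[j + 1]) if v[j] != v[j + 1] else 0.0
        widths.append(t[j] + frac * (t[j + 1] - t[j]) - tt)
    return np.asarray(widths)


# ---------------------------------------------------------------------------
# step-protocol metrics


def _require_protocol(trace: VoltageTrace) -> StimulusProtocol:
    if trace.protocol is None:
        raise ValueError("trace has no protocol annotation")
    return trace.protocol


def vmin_during_step(trace: VoltageTrace, column: int = 0) -> float:
    p = _require_protocol(trace)
    m = (trace.times_ms >= p.onset_ms) & (trace.times_ms < p.offset_ms)
    return float(trace.v_mV[m, column].min())


def rebound_delay(spikes: SpikeTrain, protocol: StimulusProtocol,
                  horizon_ms: float = REBOUND_HORIZON_MS) -> Optional[float]:
    """Seconds from step offset to the first post-offset spike peak; None
    (flagged absence) if no spike occurs within the horizon."""
    post = spikes.after(protocol.offset_ms)
    if len(post) == 0 or post.times_ms[0] > protocol.offset_ms + horizon_ms:
        return None
    return float((post.times_ms[0] - protocol.offset_ms) / 1e3)


def r_isi_frequencies(spikes: SpikeTrain, protocol: StimulusProtocol,
                      k: int = 6) -> tuple[list[float], bool]:
    """Instantaneous frequencies (1/ISI, Hz) of the first k post-offset
    intervals.  Returns (list, complete_flag); fewer than 2 post-offset
    spikes give an empty, incomplete list."""
    post = spikes.after(protocol.offset_ms)
    if len(post) < 2:
        return [], False
    isis_ms = np.diff(post.times_ms)[:k]
    return [float(1e3 / x) for x in isis_ms], len(isis_ms) == k


def sag_amplitude(trace: VoltageTrace, column: int = 0,
                  steady_state_fraction: float = 0.25) -> float:
    """Sag: steady-state mean (final fraction of the step) minus the minimum
    during the step; >= 0 by construction."""
    p = _require_protocol(trace)
    t = trace.times_ms
    v = trace.v_mV[:, column]
    inside = (t >= p.onset_ms) & (t < p.offset_ms)
    vmin = float(v[inside].min())
    ss_start = p.offset_ms - steady_state_fraction * p.duration_ms
    ss = (t >= ss_start) & (t < p.offset_ms)
    return float(v[ss].mean() - vmin)


def input_resistance(traces: Sequence[VoltageTrace],
                     steady_state_fraction: float = 0.25,
                     column: int = 0) -> PassiveMetrics:
    """Least-squares slope of steady-state delta-V versus delta-I (MOhm)
    across hyperpolarizing steps at >= 2 distinct current levels."""
    amps, dvs = [], []
    for tr in traces:
        p = _require_protocol(tr)
        t = tr.times_ms
        v = tr.v_mV[:, column]
        base = (t < p.onset_ms)
        ss = (t >= p.offset_ms - steady_state_fraction * p.duration_ms) & \
             (t < p.offset_ms)
        amps.append(p.amplitude_pA)
        dvs.append(float(v[ss].mean() - v[base].mean()))
    if len(set(amps)) < 2:
        raise ValueError("input resistance needs >= 2 distinct current levels")
    slope = np.polyfit(np.asarray(amps), np.asarray(dvs), 1)[0]  # mV/pA = GOhm
    return PassiveMetrics(input_resistance_MOhm=float(slope * 1e3),
                          vi_pairs=list(zip(amps, dvs)))


def segment_bursts(spikes: SpikeTrain | np.ndarray) -> list[list[int]]:
    """Two-threshold burst scan: a burst opens at the first of two spikes
    with ISI < 80 ms and closes before the first ISI > 160 ms.  Returns
    spike-index lists."""
    times = spikes.times_ms if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    bursts: list[list[int]] = []
    cur: list[int] = []
    for i in range(1, len(times)):
        isi = times[i] - times[i - 1]
        if not cur:
            if isi < BURST_ONSET_ISI_MS:
                cur = [i - 1, i]
        else:
            if isi > BURST_END_ISI_MS:
                bursts.append(cur)
                cur = []
                continue
            cur.append(i)
    if cur:
        bursts.append(cur)
    return bursts


def baseline_stats(spikes: SpikeTrain | np.ndarray,
                   window_ms: tuple[float, float]) -> tuple[float, float]:
    """(rate Hz, ISI CV) within a pre-stimulus window."""
    times = spikes.times_ms if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    lo, hi = window_ms
    sel = times[(times >= lo) & (times < hi)]
    rate = len(sel) / ((hi - lo) / 1e3)
    if len(sel) < 3:
        return float(rate), float("nan")
    isis = np.diff(sel)
    return float(rate), float(np.std(isis) / np.mean(isis))


def series_resistance_error(circuit: ElectrodeCircuit) -> float:
    """Percent of the measured voltage dropping across the series resistance:
    100 * Rs / (Rs + Rm)."""
    return 100.0 * circuit.rs_MOhm / (circuit.rs_MOhm + circuit.rm_MOhm)


# ---------------------------------------------------------------------------
# combined per-trial pipeline


def rebound_metrics(trace: VoltageTrace, mode: str = "invitro",
                    baseline_window_ms: Optional[tuple[float, float]] = None,
                    k: int = 6) -> ReboundMetrics:
    """Full per-trial metric extraction for an annotated step trace."""
    p = _require_protocol(trace)
    detector = detect_spikes_in_vitro if mode == "invitro" else detect_spikes_in_vivo
    spikes = detector(trace)
    window = baseline_window_ms or (0.0, p.onset_ms)
    rate, cv = baseline_stats(spikes, window)
    freqs, complete = r_isi_frequencies(spikes, p, k=k)
    return ReboundMetrics(
        vmin_mV=vmin_during_step(trace),
        rebound_delay_s=rebound_delay(spikes, p),
        r_isi_freq_hz=freqs,
        r_isi_complete=complete,
        sag_mV=sag_amplitude(trace),
        baseline_rate_hz=rate,
        baseline_cv=cv,
    )


def metrics_frame(metrics: Sequence[ReboundMetrics]) -> pd.DataFrame:
    """One row per trial with a stable column schema."""
    return pd.DataFrame([m.to_dict() for m in metrics])
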