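"""Cable-equation integration under current-injection and synaptic schedules.

Default scheme: exponential-Euler gating with a backward-Euler (Hines) voltage
solve at dt = 0.025 ms, recording decimated to 20 kHz to match experimental
sampling.  Cells are settled for 5 s before any protocol so pacemakers reach
their limit cycle; settled states can be saved and reused across protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from nigra import channels
from nigra._kernel import run_kernel, STATUS_OK
from nigra.channels import CH, CHANNEL_NAMES, N_GATES, MarkovNaScheme, build_tables
from nigra.cell import Cell

# channel-name aliases accepted by apply_pharmacology
_BLOCK_ALIASES = {
    "SK": "SK", "CAT": "CaT", "CA_T": "CaT", "TTYPE": "CaT", "T": "CaT",
    "KV4": "KA", "KV4.3": "KA", "KA": "KA", "A": "KA",
    "GIRK": "GIRK", "HCN": "HCN", "NA": "Na", "KDR": "KDR",
    "CAL": "CaL", "CAN": "CaN", "M": "M", "ERG": "ERG",
}


class SimulationError(RuntimeError):
    """Raised when the integrator diverges or a search fails to converge."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Rectangular somatic current step (pA)."""

    amplitude_pA: float
    onset_ms: float
    duration_ms: float
    site: str = "soma"  # or an integer compartment id

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be positive")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class SimulationConfig:
    dt_ms: float = 0.025
    duration_ms: float = 1000.0
    record_sites: Sequence[int] = (0,)
    record_currents: bool = False
    sample_khz: float = 20.0
    solver: str = "backward_euler"  # or "exponential_euler" (voltage update)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms < self.dt_ms:
            raise ValueError("duration must cover at least one step")
        if self.solver not in ("backward_euler", "exponential_euler"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass
class VoltageTrace:
    """Uniformly sampled voltage time series with protocol annotation.

    ``v_mV`` is (n_samples, n_sites); column 0 is the primary recording site
    (the soma unless configured otherwise).  ``currents_nA`` optionally holds
    whole-cell summed per-channel currents (outward positive).
    """

    times_ms: np.ndarray
    v_mV: np.ndarray
    sites: tuple[int, ...]
    sample_interval_ms: float
    protocol: Optional[StimulusProtocol] = None
    currents_nA: Optional[np.ndarray] = None

    @property
    def soma(self) -> np.ndarray:
        return self.v_mV[:, 0]

    @property
    def sampling_rate_khz(self) -> float:
        return 1.0 / self.sample_interval_ms

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.v_mV)):
            raise ValueError("voltage trace contains non-finite samples")

    def to_frame(self) -> pd.DataFrame:
        d = {"time_ms": self.times_ms}
        for j, s in enumerate(self.sites):
            d[f"V_mV_{s}" if j else "V_mV"] = self.v_mV[:, j]
        if self.currents_nA is not None:
            for k, name in enumerate(CHANNEL_NAMES):
                d[f"I_{name}_nA"] = self.currents_nA[:, k]
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protocol: Optional[StimulusProtocol] = None) -> "VoltageTrace":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy(float)
        vcols = [c for c in df.columns if c == "V_mV" or c.startswith("V_mV_")]
        v = df[vcols].to_numpy(float)
        return cls(times_ms=t, v_mV=v, sites=tuple(range(v.shape[1])),
                   sample_interval_ms=float(np.median(np.diff(t))), protocol=protocol)


@dataclass
class CellState:
    """Full dynamical state; reusable across integrate() calls."""

    v: np.ndarray
    gates: np.ndarray       # (10, n)
    mkst: np.ndarray        # (3, n) Markov Na occupancies
    ca_micro: np.ndarray    # uM
    ca_bulk: np.ndarray
    syn_r: np.ndarray       # (3, n) rise states, uS
    syn_d: np.ndarray       # (3, n) decay states, uS

    def copy(self) -> "CellState":
        return CellState(*(getattr(self, f).copy() for f in
                           ("v", "gates", "mkst", "ca_micro", "ca_bulk",
                            "syn_r", "syn_d")))


def init_state(cell: Cell, v0: float = -60.0) -> CellState:
    cp = cell.channel_params
    floor = cp["calcium"]["floor_uM"]
    gates = np.tile(channels.gate_steady_state(cp, v0)[:, None], (1, cell.n))
    mk = MarkovNaScheme(cp["markov_na"]).steady_state(v0)
    return CellState(
        v=np.full(cell.n, v0),
        gates=gates,
        mkst=np.tile(mk[:, None], (1, cell.n)),
        ca_micro=np.full(cell.n, floor),
        ca_bulk=np.full(cell.n, floor),
        syn_r=np.zeros((3, cell.n)),
        syn_d=np.zeros((3, cell.n)),
    )


def _syn_constants(cell: Cell, dt: float):
    """Per-step decay factors and peak normalizations for the three synapse
    types (AMPA, NMDA, GABA_A)."""
    syn = cell.channel_params["synapse"]
    rise = np.array([syn["ampa"]["tau_rise_ms"], syn["nmda"]["tau_rise_ms"],
                     syn["gaba"]["tau_rise_ms"]])
    decay = np.array([syn["ampa"]["tau_decay_ms"], syn["nmda"]["tau_decay_ms"],
                      syn["gaba"]["tau_decay_ms"]])
    # peak of exp(-t/td) - exp(-t/tr) for unit increments
    tpk = rise * decay / (decay - rise) * np.log(decay / rise)
    norm = 1.0 / (np.exp(-tpk / decay) - np.exp(-tpk / rise))
    return np.exp(-dt / rise), np.exp(-dt / decay), norm


def _stim_arrays(protocols: Sequence[StimulusProtocol], cell: Cell):
    comp = np.array([cell.soma_idx if p.site == "soma" else int(p.site)
                     for p in protocols], dtype=np.int64)
    on = np.array([p.onset_ms for p in protocols])
    off = np.array([p.offset_ms for p in protocols])
    amp = np.array([p.amplitude_pA * 1e-3 for p in protocols])  # pA -> nA
    return comp, on, off, amp


def integrate(cell: Cell,
              protocols: Sequence[StimulusProtocol] | StimulusProtocol | None = None,
              config: SimulationConfig | None = None,
              state: Optional[CellState] = None,
              events: Optional[pd.DataFrame] = None,
              record: bool = True) -> VoltageTrace:
    """Integrate the cell under the given protocol(s) and synaptic events.

    ``events`` is an event table (columns time_ms, compartment, kind, g_nS)
    as produced by :func:`nigra.invivo.generate_synaptic_schedule`.  The
    passed ``state`` is advanced in place; pass ``state.copy()`` to keep it.
    """
    cfg = config or SimulationConfig()
    if isinstance(protocols, StimulusProtocol):
        protocols = [protocols]
    protocols = list(protocols or [])
    if state is None:
        state = init_state(cell)

    dt = cfg.dt_ms
    nsteps = int(round(cfg.duration_ms / dt))
    rec_every = max(1, int(round(1.0 / (cfg.sample_khz * dt))))
    nrec = (nsteps + rec_every - 1) // rec_every

    tables = build_tables(cell.channel_params, dt, cell.tau_kv4)
    rise_exp, decay_exp, norm = _syn_constants(cell, dt)
    syn_cfg = cell.channel_params["synapse"]

    if events is not None and len(events):
        ev_step = np.floor(events["time_ms"].to_numpy(float) / dt).astype(np.int64)
        order = np.argsort(ev_step, kind="stable")
        ev_step = ev_step[order]
        ev_comp = events["compartment"].to_numpy(np.int64)[order]
        kind = events["kind"].to_numpy()[order]
        g = events["g_nS"].to_numpy(float)[order] * 1e-3  # nS -> uS
        is_e = kind == "E"
        ratio = syn_cfg["nmda_ampa_ratio"]
        ev_wa = np.where(is_e, g * norm[0], 0.0)
        ev_wn = np.where(is_e, g * ratio * norm[1], 0.0)
        ev_wg = np.where(~is_e, g * norm[2], 0.0)
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_comp = np.empty(0, dtype=np.int64)
        ev_wa = ev_wn = ev_wg = np.empty(0)

    stim_comp, stim_on, stim_off, stim_nA = _stim_arrays(protocols, cell)
    rec_idx = np.asarray(cfg.record_sites, dtype=np.int64)
    v_out = np.empty((nrec, rec_idx.size)) if record else np.empty((nrec, 0))
    rec_idx_eff = rec_idx if record else np.empty(0, dtype=np.int64)
    cur_out = np.zeros((nrec if cfg.record_currents else 1,
                        channels.N_CHANNELS))

    cal = cell.channel_params["calcium"]
    phi_micro = channels.ca_influx_factor(cal["micro_shell_depth_um"])
    phi_bulk = channels.ca_influx_factor(cal["bulk_shell_depth_um"])
    sk = cell.channel_params["sk"]

    status, step = run_kernel(
        nsteps, dt,
        cell.parent, cell.area_cm2, cell.g_ax_uS, cell.cm_nF,
        cell.gdens, cell.erev,
        channels.V_MIN, channels.V_STEP,
        tables.xinf, tables.xexp, tables.mk, tables.mg_block,
        cell.f_coupling, cell.tau_micro, phi_micro,
        cal["bulk_tau_ms"], phi_bulk, cal["floor_uM"],
        sk["kd_uM"], sk["hill"],
        rise_exp, decay_exp,
        syn_cfg["ampa"]["e_mV"], syn_cfg["gaba"]["e_mV"],
        ev_step, ev_comp, ev_wa, ev_wn, ev_wg,
        stim_comp, stim_on, stim_off, stim_nA,
        state.v, state.gates, state.mkst, state.ca_micro, state.ca_bulk,
        state.syn_r, state.syn_d,
        rec_every, rec_idx_eff, v_out, cur_out, cfg.record_currents,
        cfg.solver == "exponential_euler",
    )
    if status != STATUS_OK:
        raise SimulationError(
            f"integration diverged at t = {step * dt:.3f} ms "
            f"(|V| > 200 mV); dt = {dt} ms, {len(protocols)} stimuli"
        )
    if not record:
        return None  # type: ignore[return-value]
    times = np.arange(nrec) * rec_every * dt
    return VoltageTrace(
        times_ms=times,
        v_mV=v_out,
        sites=tuple(int(i) for i in rec_idx),
        sample_interval_ms=rec_every * dt,
        protocol=protocols[0] if protocols else None,
        currents_nA=cur_out if cfg.record_currents else None,
    )


def settle(cell: Cell, duration_ms: float = 5000.0, v0: float = -60.0,
           dt_ms: float = 0.025) -> CellState:
    """Unrecorded settling run; returns the state at its end."""
    state = init_state(cell, v0=v0)
    integrate(cell, [], SimulationConfig(dt_ms=dt_ms, duration_ms=duration_ms),
              state=state, record=False)
    return state


def apply_pharmacology(cell: Cell, block_spec: dict[str, float]) -> Cell:
    """Return a copy with named conductances scaled by (1 - block fraction).

    Accepts the channel names used in the protocols: SK, CaT, Kv4 (or KA),
    GIRK, HCN, Na, KDR, CaL, CaN, M, ERG.
    """
    out = cell.copy()
    for name, frac in block_spec.items():
        key = _BLOCK_ALIASES.get(name.upper().replace(" ", ""))
        if key is None:
            raise KeyError(f"unknown channel {name!r} in block spec")
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"block fraction for {name} must be in [0, 1]")
        out.gdens[CH[key]] *= (1.0 - frac)
    return out


def titrate_hyperpolarizing_current(
    cell: Cell,
    state: CellState,
    target_vmin_mV: float = -80.0,
    duration_ms: float = 2000.0,
    tol_mV: float = 0.5,
    max_iter: int = 30,
    amp_bracket_pA: tuple[float, float] = (-800.0, 0.0),
    dt_ms: float = 0.025,
) -> tuple[float, float]:
    """Bisect the step amplitude until the somatic minimum during the step is
    within tolerance of the target; returns (amplitude_pA, achieved_vmin).

    The supplied settled state is never modified (each probe runs on a copy).
    """

    def vmin_for(amp: float) -> float:
        proto = StimulusProtocol(amplitude_pA=amp, onset_ms=50.0,
                                 duration_ms=duration_ms)
        cfg = SimulationConfig(dt_ms=dt_ms, duration_ms=duration_ms + 100.0,
                               record_sites=(cell.soma_idx,))
        try:
            tr = integrate(cell, proto, cfg, state=state.copy())
        except SimulationError:
            # over-strong probe drove the cable out of range: report it as far
            # below any physiological target so bisection backs off
            return -1000.0
        inside = (tr.times_ms >= proto.onset_ms) & (tr.times_ms < proto.offset_ms)
        return float(tr.soma[inside].min())

    lo, hi = amp_bracket_pA  # lo: strong hyperpolarization, hi: none
    v_lo = vmin_for(lo)
    if v_lo > target_vmin_mV:
        raise SimulationError(
            f"bracket too weak: {lo} pA reaches only {v_lo:.1f} mV"
        )
    amp = lo
    for _ in range(max_iter):
        amp = 0.5 * (lo + hi)
        vm = vmin_for(amp)
        if abs(vm - target_vmin_mV) <= tol_mV:
            return amp, vm
        if vm > target_vmin_mV:  # not hyperpolarized enough
            hi = amp
        else:
            lo = amp
    raise SimulationError(
        f"titration did not converge within {max_iter} iterations "
        f"(last amplitude {amp:.1f} pA)"
    )


def rebound_protocol(cell: Cell,
                     target_vmin_mV: float = -80.0,
                     step_duration_ms: float = 2000.0,
                     baseline_ms: float = 3000.0,
                     post_ms: float = 3000.0,
                     settle_ms: float = 5000.0,
                     state: Optional[CellState] = None,
                     record_currents: bool = False,
                     dt_ms: float = 0.025) -> VoltageTrace:
    """Run the standard in-vitro rebound experiment on one cell.

    Settles, titrates a hyperpolarizing step of the given duration to the
    target minimum, then records baseline, step and post-release windows in
    one trace whose protocol annotation carries the titrated amplitude.
    """
    if state is None:
        state = settle(cell, duration_ms=settle_ms, dt_ms=dt_ms)
    amp, _ = titrate_hyperpolarizing_current(
        cell, state, target_vmin_mV=target_vmin_mV,
        duration_ms=step_duration_ms, dt_ms=dt_ms)
    proto = StimulusProtocol(amplitude_pA=amp, onset_ms=baseline_ms,
                             duration_ms=step_duration_ms)
    cfg = SimulationConfig(
        dt_ms=dt_ms, duration_ms=baseline_ms + step_duration_ms + post_ms,
        record_sites=(cell.soma_idx,), record_currents=record_currents)
    return integrate(cell, proto, cfg, state=state.copy())


# ---------------------------------------------------------------------------
# reference single step (oracle for charge-conservation tests)


def reference_step(cell: Cell, state: CellState, dt: float,
                   inj_nA: np.ndarray | None = None):
    """One staggered step computed with dense numpy linear algebra.

    Mirrors the scheme of the compiled kernel through an independent code
    path (exact rate functions instead of lookup tables, dense matrix solve
    instead of Hines elimination).  Returns (new_state, A, b) where A v_new
    = b is the assembled backward-Euler system in (uS, nA) units, so tests
    can check Kirchhoff's current law on the solution directly.
    """
    cp = cell.channel_params
    specs = channels.build_gate_specs(cp)
    scheme = MarkovNaScheme(cp["markov_na"])
    s = state.copy()
    n = cell.n
    v = s.v.copy()
    inj = np.zeros(n) if inj_nA is None else np.asarray(inj_nA, float)

    for i in range(n):
        for g, name in enumerate(channels.GATE_NAMES):
            spec = specs[name]
            tau = cell.tau_kv4 if name == "ka_b" else float(spec.tau(v[i]))
            xi = float(spec.xinf(v[i]))
            s.gates[g, i] = xi + (s.gates[g, i] - xi) * math.exp(-dt / tau)
        s.mkst[:, i] = channels.step_markov_na(s.mkst[:, i], scheme, v[i], dt)

    gate = s.gates
    o = np.zeros((channels.N_CHANNELS, n))
    o[CH["Na"]] = s.mkst[1]
    o[CH["KDR"]] = gate[0] ** 3
    o[CH["KA"]] = gate[1] ** 2 * gate[2]
    o[CH["HCN"]] = gate[3]
    o[CH["CaT"]] = gate[4] ** 2 * gate[5]
    o[CH["CaL"]] = gate[6] * gate[7]
    o[CH["CaN"]] = gate[8] ** 2
    sk = cp["sk"]
    o[CH["SK"]] = channels.sk_open_fraction(s.ca_micro, sk["kd_uM"], sk["hill"])
    o[CH["M"]] = gate[9]
    o[CH["ERG"]] = gate[10]
    o[CH["GIRK"]] = o[CH["NaL"]] = o[CH["KL"]] = 1.0

    i_cat = channels.channel_current(cell.gdens[CH["CaT"]], o[CH["CaT"]], v,
                                     cell.erev[CH["CaT"]])
    i_cal = channels.channel_current(cell.gdens[CH["CaL"]], o[CH["CaL"]], v,
                                     cell.erev[CH["CaL"]])
    i_can = channels.channel_current(cell.gdens[CH["CaN"]], o[CH["CaN"]], v,
                                     cell.erev[CH["CaN"]])
    cal = cp["calcium"]
    pools = channels.CalciumPools(s.ca_micro, s.ca_bulk, cal["floor_uM"])
    pools = channels.update_calcium(
        pools, i_can, i_cat, i_cal, cell.f_coupling, dt,
        cell.tau_micro, channels.ca_influx_factor(cal["micro_shell_depth_um"]),
        cal["bulk_tau_ms"], channels.ca_influx_factor(cal["bulk_shell_depth_um"]))
    s.ca_micro, s.ca_bulk = pools.ca_micro, pools.ca_bulk

    sca = cell.area_cm2 * 1e3  # density mS/cm^2 -> uS
    g_abs = cell.gdens * o * sca  # (13, n) uS
    gtot = g_abs.sum(axis=0)
    ge = (g_abs * cell.erev[:, None]).sum(axis=0)

    A = np.zeros((n, n))
    b = cell.cm_nF / dt * v + ge + inj
    for i in range(n):
        A[i, i] = cell.cm_nF[i] / dt + gtot[i]
    for i in range(n):
        p = cell.parent[i]
        if p >= 0:
            A[i, i] += cell.g_ax_uS[i]
            A[p, p] += cell.g_ax_uS[i]
            A[i, p] -= cell.g_ax_uS[i]
            A[p, i] -= cell.g_ax_uS[i]
    s.v = np.linalg.solve(A, b)
    return s, A, b
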