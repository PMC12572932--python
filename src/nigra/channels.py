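"""Membrane mechanisms: HH-style gates, the reduced Markov Na scheme, SK
activation and the two-pool calcium handling with fractional CaT->SK coupling.

All kinetic constants live in ``data/channel_params.yaml`` (versioned); this
module turns them into callables, voltage lookup tables for the integrator,
and small reference steppers used by the test oracles.

Sign convention: outward current positive; conductance densities in mS/cm^2
internally (the parameter file and the sampled ranges use uS/cm^2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

FARADAY = 96485.33212  # C/mol

# canonical channel ordering shared with the integrator kernel
CHANNEL_NAMES = (
    "Na", "KDR", "KA", "HCN", "CaT", "CaL", "CaN",
    "SK", "M", "ERG", "GIRK", "NaL", "KL",
)
CH = {name: i for i, name in enumerate(CHANNEL_NAMES)}
N_CHANNELS = len(CHANNEL_NAMES)

GATE_NAMES = ("kdr_n", "ka_a", "ka_b", "hcn_h", "cat_m",
              "cat_h", "cal_m", "cal_h", "can_m", "m_m", "erg_o")
N_GATES = len(GATE_NAMES)

# voltage grid for the kinetics lookup tables
V_MIN, V_MAX, V_STEP = -130.0, 70.0, 0.05


_ALLOWED_TOP_KEYS = {
    "version", "membrane", "reversal_mV", "gates", "markov_na", "sk",
    "calcium", "tuned_densities_uS_cm2", "spatial", "synapse",
}


def load_channel_params(path=None) -> dict:
    """Load the canonical channel parameter file; unknown top-level keys are
    rejected so stale or typo'd files fail loudly."""
    if path is None:
        ref = importlib.resources.files("nigra").joinpath("data/channel_params.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    params = yaml.safe_load(text)
    unknown = set(params) - _ALLOWED_TOP_KEYS
    if unknown:
        raise ValueError(f"unknown keys in channel parameter file: {sorted(unknown)}")
    return params


@dataclass(frozen=True)
class GateSpec:
    """Voltage-dependent steady state and time constant of one HH gate."""

    name: str
    vhalf: float
    k: float
    power: int
    tau_min: float
    tau_amp: float
    vt: float
    ka: float
    kb: float

    def xinf(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.vhalf) / self.k))

    def tau(self, v):
        v = np.asarray(v, float)
        if self.tau_amp == 0.0:
            return np.full_like(v, self.tau_min)
        return self.tau_min + self.tau_amp / (
            np.exp((v - self.vt) / self.ka) + np.exp(-(v - self.vt) / self.kb)
        )


def build_gate_specs(params: dict) -> dict[str, GateSpec]:
    return {name: GateSpec(name=name, **params["gates"][name]) for name in GATE_NAMES}


# ---------------------------------------------------------------------------
# Markov sodium scheme


def _sig(v, r, vhalf, k):
    return r / (1.0 + np.exp(-(np.asarray(v, float) - vhalf) / k))


@dataclass(frozen=True)
class MarkovNaScheme:
    """Reduced 3-state (C, O, I) sodium scheme.

    Transitions: C<->O (activation/deactivation), O->I (open-state
    inactivation), I->C (recovery), C->I (closed-state inactivation).
    """

    rates: dict  # name -> {r, vhalf, k}

    N_STATES = 3  # order: C, O, I

    def rate(self, name: str, v):
        p = self.rates[name]
        return _sig(v, p["r"], p["vhalf"], p["k"])

    def rate_matrix(self, v: float) -> np.ndarray:
        """Generator matrix Q with dx/dt = Q @ x, columns summing to zero."""
        a = float(self.rate("a_co", v))
        b = float(self.rate("b_oc", v))
        koi = float(self.rate("k_oi", v))
        kic = float(self.rate("k_ic", v))
        kci = float(self.rate("k_ci", v))
        return np.array([
            [-(a + kci), b,          kic],
            [a,          -(b + koi), 0.0],
            [kci,        koi,        -kic],
        ])

    def steady_state(self, v: float) -> np.ndarray:
        """Null-space eigenvector of Q(v), normalized to sum 1."""
        w, vec = np.linalg.eig(self.rate_matrix(v))
        i = int(np.argmin(np.abs(w)))
        x = np.real(vec[:, i])
        return x / x.sum()


def step_markov_na(state: np.ndarray, scheme: MarkovNaScheme, v: float,
                   dt: float) -> np.ndarray:
    """Advance occupancies by one implicit-Euler step of the master equation.

    The implicit update (I - dt*Q) x_new = x_old preserves the occupancy sum
    exactly (up to roundoff) and is unconditionally stable.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if dt == 0:
        return state.copy()
    q = scheme.rate_matrix(v)
    return np.linalg.solve(np.eye(3) - dt * q, state)


# ---------------------------------------------------------------------------
# SK activation and calcium pools


def sk_open_fraction(ca_micro, kd: float = 0.35, hill: float = 4.0):
    """Hill activation of SK by microdomain calcium (uM); 0.5 at ca == kd."""
    ca = np.maximum(np.asarray(ca_micro, float), 0.0)
    can = ca ** hill
    return can / (can + kd ** hill)


def ca_influx_factor(shell_depth_um: float) -> float:
    """uM per ms of concentration change per uA/cm^2 of inward Ca current
    entering a shell of the given depth (single-sided, no buffering)."""
    depth_cm = shell_depth_um * 1e-4
    # mol/(cm^2 ms) per uA/cm^2 = 1e-9/(2F); /depth -> mol/cm^3; *1e9 -> uM... :
    # 1 mol/cm^3 = 1e3 mol/L = 1e9 uM
    return 1e-9 / (2.0 * FARADAY) / depth_cm * 1e9


@dataclass
class CalciumPools:
    """Microdomain (read by SK) and bulk calcium, in uM."""

    ca_micro: np.ndarray
    ca_bulk: np.ndarray
    floor: float = 0.05


def update_calcium(pools: CalciumPools, i_can, i_cat, i_cal, f: float,
                   dt: float, tau_micro: float, phi_micro: float,
                   tau_bulk: float, phi_bulk: float) -> CalciumPools:
    """One exponential-Euler step of both pools.

    The microdomain sees CaN influx plus fraction ``f`` of CaT influx (CaL is
    purely electrogenic and contributes nothing); the bulk pool sees all Ca
    currents.  Inward currents are negative, so influx is max(0, -I).
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    if not (0.0 <= f <= 1.0):
        raise ValueError("coupling fraction f must lie in [0, 1]")
    influx_micro = phi_micro * (np.maximum(0.0, -np.asarray(i_can, float))
                                + f * np.maximum(0.0, -np.asarray(i_cat, float)))
    influx_bulk = phi_bulk * (np.maximum(0.0, -np.asarray(i_can, float))
                              + np.maximum(0.0, -np.asarray(i_cat, float))
                              + np.maximum(0.0, -np.asarray(i_cal, float)))

    def _step(ca, influx, tau):
        target = pools.floor + influx * tau
        return target + (ca - target) * np.exp(-dt / tau)

    return CalciumPools(
        ca_micro=_step(pools.ca_micro, influx_micro, tau_micro),
        ca_bulk=_step(pools.ca_bulk, influx_bulk, tau_bulk),
        floor=pools.floor,
    )


# ---------------------------------------------------------------------------
# ohmic current and lookup tables for the integrator


def channel_current(g_mS_cm2, open_fraction, v, e_rev):
    """Ohmic current density g*o*(V-E) in uA/cm^2 (outward positive)."""
    return np.asarray(g_mS_cm2, float) * np.asarray(open_fraction, float) * (
        np.asarray(v, float) - e_rev
    )


@dataclass
class KineticsTables:
    """Voltage lookup tables consumed by the compiled integrator.

    xinf/xexp rows follow GATE_NAMES; the ka_b (Kv4 inactivation) xexp row is
    filled per cell from its sampled time constant.  mk rows are the five
    Markov rates in the order (a_co, b_oc, k_oi, k_ic, k_ci).
    """

    v_grid: np.ndarray
    xinf: np.ndarray       # (N_GATES, nV)
    xexp: np.ndarray       # (N_GATES, nV), exp(-dt/tau) for fixed dt
    mk: np.ndarray         # (5, nV) rates 1/ms
    mg_block: np.ndarray   # (nV,) NMDA Mg unblock factor
    dt: float


def build_tables(params: dict, dt: float, tau_kv4_ms: float) -> KineticsTables:
    v = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
    specs = build_gate_specs(params)
    xinf = np.empty((N_GATES, v.size))
    xexp = np.empty((N_GATES, v.size))
    for i, name in enumerate(GATE_NAMES):
        spec = specs[name]
        xinf[i] = spec.xinf(v)
        tau = np.full(v.size, tau_kv4_ms) if name == "ka_b" else spec.tau(v)
        xexp[i] = np.exp(-dt / tau)
    scheme = MarkovNaScheme(params["markov_na"])
    mk = np.vstack([scheme.rate(k, v)
                    for k in ("a_co", "b_oc", "k_oi", "k_ic", "k_ci")])
    mg = params["synapse"]["nmda"]["mg_mM"]
    mg_block = 1.0 / (1.0 + mg / 3.57 * np.exp(-0.062 * v))
    return KineticsTables(v_grid=v, xinf=xinf, xexp=xexp, mk=mk,
                          mg_block=mg_block, dt=dt)


def gate_steady_state(params: dict, v: float) -> np.ndarray:
    specs = build_gate_specs(params)
    return np.array([float(specs[name].xinf(v)) for name in GATE_NAMES])
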