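"""Projection-specific cell construction.

Samples per-class parameter sets (channel density ranges, Kv4 inactivation
time constant, CaT->SK coupling fraction f, microdomain time constant) from
independent uniform distributions, lays conductances onto the shared
morphology following the spatial rules (no CaT within 150 um of the soma,
5x Kv4 in the soma, 5x spiking conductances in the AIS, elevated HCN on the
ABD, distal attenuation of spiking conductances), and validates assembled
cells against the action-potential tuning criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional

import numpy as np
import yaml

from nigra import channels
from nigra.channels import CH, N_CHANNELS, load_channel_params
from nigra.morphology import Morphology, MorphologyConfig, Region, build_morphology


class ProjectionClass(str, Enum):
    DLS = "DLS"
    DMS = "DMS"
    lNAcc = "lNAcc"


@dataclass(frozen=True)
class ParameterRanges:
    """Per-class (min, max) sampling intervals; densities in uS/cm^2, taus ms.

    The Na and K leak conductances are varied in tandem (one shared draw)
    so their sum stays at the class constant.  The somatic Kv4 density is
    5x the dendritic draw (fixed ratio across distances).
    """

    gna_l: tuple[float, float]
    gk_l: tuple[float, float]
    tau_kv4: tuple[float, float]
    gkv4_dend: tuple[float, float]
    gcat_distal: tuple[float, float]
    gsk: tuple[float, float]
    ghcn: tuple[float, float]
    ggirk_invitro: float
    ggirk_invivo: tuple[float, float]
    f_coupling: tuple[float, float]
    tau_micro: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("gna_l", "gk_l", "tau_kv4", "gkv4_dend", "gcat_distal",
                     "gsk", "ghcn", "ggirk_invivo", "f_coupling", "tau_micro"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: min > max")

    @property
    def leak_sum(self) -> float:
        return self.gna_l[0] + self.gk_l[1]


# Density ranges per projection class.  The leak, Kv4, CaT, SK, HCN and GIRK
# intervals are the tabulated per-class model parameters; the coupling
# fraction f and the microdomain time constant are modelling choices (smaller
# microdomain timescale and weaker CaT->SK coupling for DLS, reflecting the
# reduced Ca-channel/SK coupling of that class).
PARAMETER_RANGES: dict[ProjectionClass, ParameterRanges] = {
    ProjectionClass.DLS: ParameterRanges(
        gna_l=(3.5, 4.5), gk_l=(6.0, 7.0), tau_kv4=(25.0, 50.0),
        gkv4_dend=(135.0, 225.0), gcat_distal=(350.0, 450.0),
        gsk=(75.0, 150.0), ghcn=(15.0, 20.0),
        ggirk_invitro=20.0, ggirk_invivo=(10.0, 30.0),
        f_coupling=(0.08, 0.16), tau_micro=(5.0, 10.0),
    ),
    ProjectionClass.DMS: ParameterRanges(
        gna_l=(4.0, 5.0), gk_l=(6.0, 7.0), tau_kv4=(75.0, 125.0),
        gkv4_dend=(225.0, 360.0), gcat_distal=(150.0, 250.0),
        gsk=(100.0, 200.0), ghcn=(15.0, 20.0),
        ggirk_invitro=20.0, ggirk_invivo=(10.0, 30.0),
        f_coupling=(0.5, 0.9), tau_micro=(15.0, 30.0),
    ),
    ProjectionClass.lNAcc: ParameterRanges(
        gna_l=(4.0, 5.0), gk_l=(6.0, 7.0), tau_kv4=(60.0, 100.0),
        gkv4_dend=(225.0, 360.0), gcat_distal=(150.0, 250.0),
        gsk=(100.0, 200.0), ghcn=(15.0, 20.0),
        ggirk_invitro=20.0, ggirk_invivo=(10.0, 30.0),
        f_coupling=(0.5, 0.9), tau_micro=(15.0, 30.0),
    ),
}


@dataclass
class CellParameters:
    """One sampled, projection-specific parameter set (uS/cm^2, ms)."""

    projection: ProjectionClass
    seed: int
    gna_l: float
    gk_l: float
    tau_kv4: float
    gkv4_dend: float
    gkv4_soma: float
    gcat_distal: float
    gsk: float
    ghcn: float
    ggirk: float
    f_coupling: float
    tau_micro: float
    in_vivo: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["projection"] = self.projection.value
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "CellParameters":
        d = dict(d)
        d["projection"] = ProjectionClass(d["projection"])
        return cls(**d)


def sample_parameters(projection: ProjectionClass, rng_seed: int,
                      in_vivo: bool = False) -> CellParameters:
    """Draw one parameter set; deterministic given (projection, seed).

    All draws are independent uniforms except the leaks, which share a single
    draw u with gNa_L = lo + u*span and gK_L = hi - u*span so their sum is
    the class constant for every u.
    """
    projection = ProjectionClass(projection)
    r = PARAMETER_RANGES[projection]
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform()
    gna_l = r.gna_l[0] + u * (r.gna_l[1] - r.gna_l[0])
    gk_l = r.gk_l[1] - u * (r.gk_l[1] - r.gk_l[0])
    tau_kv4 = rng.uniform(*r.tau_kv4)
    gkv4_dend = rng.uniform(*r.gkv4_dend)
    gcat = rng.uniform(*r.gcat_distal)
    gsk = rng.uniform(*r.gsk)
    ghcn = rng.uniform(*r.ghcn)
    ggirk_vivo = rng.uniform(*r.ggirk_invivo)
    f_cpl = rng.uniform(*r.f_coupling)
    tau_micro = rng.uniform(*r.tau_micro)
    ratio = channels.load_channel_params()["spatial"]["kv4_soma_dendrite_ratio"]
    return CellParameters(
        projection=projection, seed=int(rng_seed),
        gna_l=gna_l, gk_l=gk_l, tau_kv4=tau_kv4,
        gkv4_dend=gkv4_dend, gkv4_soma=ratio * gkv4_dend,
        gcat_distal=gcat, gsk=gsk, ghcn=ghcn,
        ggirk=ggirk_vivo if in_vivo else r.ggirk_invitro,
        f_coupling=f_cpl, tau_micro=tau_micro, in_vivo=in_vivo,
    )


# ---------------------------------------------------------------------------
# assembled cell


@dataclass
class Cell:
    """A fully assembled model cell: geometry arrays plus per-compartment
    channel densities, ready for the integrator.

    ``gdens`` rows follow :data:`nigra.channels.CHANNEL_NAMES` (mS/cm^2).
    """

    n: int
    parent: np.ndarray       # (n,) int64
    area_cm2: np.ndarray     # (n,)
    g_ax_uS: np.ndarray      # (n,) axial conductance to parent
    cm_nF: np.ndarray        # (n,)
    gdens: np.ndarray        # (13, n) mS/cm^2
    erev: np.ndarray         # (13,) mV
    tau_kv4: float
    f_coupling: float
    tau_micro: float
    channel_params: dict
    morph: Optional[Morphology] = None
    params: Optional[CellParameters] = None
    soma_idx: int = 0
    ais_idx: int = -1

    def copy(self) -> "Cell":
        return Cell(
            n=self.n, parent=self.parent.copy(), area_cm2=self.area_cm2.copy(),
            g_ax_uS=self.g_ax_uS.copy(), cm_nF=self.cm_nF.copy(),
            gdens=self.gdens.copy(), erev=self.erev.copy(),
            tau_kv4=self.tau_kv4, f_coupling=self.f_coupling,
            tau_micro=self.tau_micro, channel_params=self.channel_params,
            morph=self.morph, params=self.params,
            soma_idx=self.soma_idx, ais_idx=self.ais_idx,
        )

    def total_conductance_leak_uS(self) -> float:
        """Summed leak+GIRK conductance, a quick Rin sanity scale."""
        g = (self.gdens[CH["NaL"]] + self.gdens[CH["KL"]] + self.gdens[CH["GIRK"]])
        return float(np.sum(g * self.area_cm2) * 1e3)


def _axial_conductances(morph: Morphology) -> np.ndarray:
    """uS conductance between each compartment center and its parent's."""
    ra = morph.axial_resistivity  # Ohm*cm
    comps = morph.compartments
    g = np.zeros(len(comps))

    def half_res_ohm(c):  # Ra * (L/2) / (pi r^2), lengths in cm
        length_cm = c.length * 1e-4 / 2.0
        radius_cm = c.diameter * 1e-4 / 2.0
        return ra * length_cm / (math.pi * radius_cm ** 2)

    for c in comps:
        if c.parent_id is None:
            continue
        r_total = half_res_ohm(c) + half_res_ohm(comps[c.parent_id])
        g[c.id] = 1e6 / r_total
    return g


def distribute_conductances(morph: Morphology, params: CellParameters,
                            channel_params: dict | None = None) -> np.ndarray:
    """Per-compartment maximal conductance densities (13, n) in mS/cm^2.

    Spatial rules: CaT zero within 150 um of the soma and at the sampled
    density beyond; Kv4 somatic value in the soma, dendritic value elsewhere;
    HCN elevated on ABD compartments; spiking gNa/gKDR 5x in the AIS and
    linearly attenuated with path distance to 20% at the most distal segment.
    """
    cp = channel_params or load_channel_params()
    tuned = cp["tuned_densities_uS_cm2"]
    spatial = cp["spatial"]
    n = len(morph)
    regions = morph.regions
    dist = morph.path_distances()
    gdens = np.zeros((N_CHANNELS, n))

    u = 1e-3  # uS/cm^2 -> mS/cm^2
    gdens[CH["NaL"]] = params.gna_l * u
    gdens[CH["KL"]] = params.gk_l * u
    gdens[CH["SK"]] = params.gsk * u
    gdens[CH["GIRK"]] = params.ggirk * u
    gdens[CH["CaL"]] = tuned["gcal"] * u
    gdens[CH["CaN"]] = tuned["gcan"] * u
    gdens[CH["M"]] = tuned["gm"] * u
    gdens[CH["ERG"]] = tuned["gerg"] * u

    hcn = np.full(n, params.ghcn * u)
    kv4 = np.full(n, params.gkv4_dend * u)
    cat = np.where(dist < spatial["cat_min_distance_um"], 0.0, params.gcat_distal * u)

    dend_ids = [i for i, r in enumerate(regions) if r not in (Region.SOMA, Region.AIS)]
    max_dist = max(dist[i] for i in dend_ids)
    distal_frac = spatial["distal_spiking_fraction"]
    spike_scale = np.clip(1.0 - (1.0 - distal_frac) * dist / max_dist, distal_frac, 1.0)

    for i, r in enumerate(regions):
        if r is Region.SOMA:
            kv4[i] = params.gkv4_soma * u
            spike_scale[i] = 1.0
        elif r is Region.AIS:
            spike_scale[i] = spatial["ais_spiking_factor"]
            cat[i] = 0.0
        elif r is Region.ABD:
            hcn[i] *= spatial["abd_hcn_factor"]

    gdens[CH["HCN"]] = hcn
    gdens[CH["KA"]] = kv4
    gdens[CH["CaT"]] = cat
    gdens[CH["Na"]] = tuned["gna"] * u * spike_scale
    gdens[CH["KDR"]] = tuned["gkdr"] * u * spike_scale
    return gdens


def build_cell(params: CellParameters,
               morph_config: MorphologyConfig | None = None,
               channel_params: dict | None = None) -> Cell:
    """Assemble a ready-to-integrate cell from a sampled parameter set."""
    cp = channel_params or load_channel_params()
    morph = build_morphology(morph_config)
    gdens = distribute_conductances(morph, params, cp)
    rev = cp["reversal_mV"]
    erev = np.empty(N_CHANNELS)
    for name, e in (("Na", rev["na"]), ("KDR", rev["k"]), ("KA", rev["k"]),
                    ("HCN", rev["h"]), ("CaT", rev["ca"]), ("CaL", rev["ca"]),
                    ("CaN", rev["ca"]), ("SK", rev["k"]), ("M", rev["k"]),
                    ("ERG", rev["k"]), ("GIRK", rev["k"]), ("NaL", rev["na"]),
                    ("KL", rev["k"])):
        erev[CH[name]] = e
    area = morph.surface_areas() * 1e-8  # um^2 -> cm^2
    cm = cp["membrane"]["capacitance_uF_cm2"]
    return Cell(
        n=len(morph),
        parent=morph.parent_index,
        area_cm2=area,
        g_ax_uS=_axial_conductances(morph),
        cm_nF=cm * area * 1e3,
        gdens=gdens,
        erev=erev,
        tau_kv4=params.tau_kv4,
        f_coupling=params.f_coupling,
        tau_micro=params.tau_micro,
        channel_params=cp,
        morph=morph,
        params=params,
        soma_idx=morph.soma_id,
        ais_idx=morph.ais_id,
    )


def make_cell(projection: ProjectionClass | str, seed: int,
              in_vivo: bool = False,
              morph_config: MorphologyConfig | None = None) -> Cell:
    """Sample parameters and assemble in one call."""
    return build_cell(sample_parameters(ProjectionClass(projection), seed,
                                        in_vivo=in_vivo),
                      morph_config=morph_config)


# ---------------------------------------------------------------------------
# tuning validation


@dataclass
class TuningReport:
    """Spike-shape and pacemaking diagnostics against the tuning criteria."""

    silent: bool
    baseline_rate_hz: float
    peak_mV: Optional[float]
    threshold_mV: Optional[float]
    width_ms: Optional[float]
    initiation_site: Optional[str]
    peak_ok: bool = False
    threshold_ok: bool = False
    width_ok: bool = False
    initiation_ok: bool = False

    @property
    def passed(self) -> bool:
        return (not self.silent and self.peak_ok and self.threshold_ok
                and self.width_ok and self.initiation_ok)


def validate_tuning(cell: Cell, duration_ms: float = 4000.0,
                    threshold_tol_mV: float = 3.0,
                    width_tol_ms: float = 0.5) -> TuningReport:
    """Simulate unperturbed pacemaking and check the AP criteria.

    Criteria: peak in [+10, +30] mV, threshold within tolerance of -40 mV,
    width at threshold within tolerance of 2 ms, spike initiation in the AIS
    (AIS upstroke precedes the somatic one).  A non-spiking cell yields a
    structured silent report.
    """
    from nigra import simulate as sim
    from nigra import analysis

    state = sim.settle(cell)
    cfg = sim.SimulationConfig(duration_ms=duration_ms,
                               record_sites=(cell.soma_idx, cell.ais_idx))
    trace = sim.integrate(cell, [], cfg, state=state)
    spikes = analysis.detect_spikes_in_vitro(trace, filter_first=False)
    if len(spikes) < 2:
        return TuningReport(silent=True, baseline_rate_hz=0.0, peak_mV=None,
                            threshold_mV=None, width_ms=None, initiation_site=None)

    rate = (len(spikes) - 1) / ((spikes.times_ms[-1] - spikes.times_ms[0]) / 1e3)
    peak = float(np.mean(spikes.peaks_mV))
    thr = float(np.mean(spikes.thresholds_mV))
    widths = analysis.spike_widths_at_threshold(trace, spikes)
    width = float(np.nanmean(widths)) if len(widths) else float("nan")

    # initiation: compare the earliest 10 mV/ms upstroke crossing near each
    # somatic spike between the AIS and soma traces
    t = trace.times_ms
    v_soma = trace.v_mV[:, 0]
    v_ais = trace.v_mV[:, 1]
    dt = trace.sample_interval_ms
    dv_soma = np.gradient(v_soma, dt)
    dv_ais = np.gradient(v_ais, dt)
    leads = []
    for st in spikes.times_ms:
        sel = (t >= st - 3.0) & (t <= st + 1.0)
        cs = np.flatnonzero((dv_soma >= 10.0) & sel)
        ca = np.flatnonzero((dv_ais >= 10.0) & sel)
        if len(cs) and len(ca):
            leads.append(t[cs[0]] - t[ca[0]])
    initiation = "AIS" if (leads and np.median(leads) > 0) else "soma"

    return TuningReport(
        silent=False,
        baseline_rate_hz=float(rate),
        peak_mV=peak,
        threshold_mV=thr,
        width_ms=width,
        initiation_site=initiation,
        peak_ok=10.0 <= peak <= 30.0,
        threshold_ok=abs(thr - (-40.0)) <= threshold_tol_mV,
        width_ok=abs(width - 2.0) <= width_tol_ms,
        initiation_ok=initiation == "AIS",
    )
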