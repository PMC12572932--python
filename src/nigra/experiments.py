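"""Figure-level computational experiments from declarative configs.

Each experiment runs sampling -> building -> (optional tuning gate) ->
protocol simulation -> metric extraction -> population summary, writes
tabular outputs plus a manifest with seeds, content hashes and the package
version, and is fully deterministic per config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from nigra import analysis, invivo
from nigra import simulate as sim
from nigra.cell import (Cell, ProjectionClass, build_cell, sample_parameters,
                        validate_tuning)

log = logging.getLogger("nigra.experiments")

EXPERIMENT_IDS = (
    "fig7_invitro",
    "fig7_pharma_SK", "fig7_pharma_CaT", "fig7_pharma_Kv4", "fig7_pharma_GIRK",
    "figS3_durations",
    "fig9_invivo",
)

_PHARMA_BLOCKS = {
    "fig7_pharma_SK": {"SK": 1.0},
    "fig7_pharma_CaT": {"CaT": 1.0},
    "fig7_pharma_Kv4": {"Kv4": 1.0},
    "fig7_pharma_GIRK": {"GIRK": 1.0},
}


@dataclass
class ExperimentConfig:
    experiment: str
    projections: Sequence[str] = ("DLS", "DMS", "lNAcc")
    n_cells: int = 11
    seed: int = 42
    scale: float = 1.0            # shrink population sizes for quick runs
    out_dir: str = "results"
    target_vmin_mV: float = -80.0
    step_duration_ms: float = 2000.0
    durations_ms: Sequence[float] = (100, 200, 300, 500, 1000, 1500, 2000)
    tuning_gate: bool = False
    retry_cap: int = 3

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment id {self.experiment!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def effective_n(self) -> int:
        return max(1, int(round(self.n_cells * self.scale)))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _cell_seeds(master_seed: int, n: int) -> list[int]:
    """Documented splitting scheme: SeedSequence(master) state stream."""
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n) % (2 ** 31)]


def _sample_gated(projection: ProjectionClass, seed: int, cfg: ExperimentConfig):
    """Sample a cell, optionally rejecting tuning-criteria failures with a
    bounded number of reseeded retries."""
    for attempt in range(cfg.retry_cap + 1):
        params = sample_parameters(projection, seed + 7919 * attempt)
        cell = build_cell(params)
        if not cfg.tuning_gate:
            return cell
        report = validate_tuning(cell)
        if report.passed:
            return cell
        log.warning("tuning gate rejected %s seed %d (attempt %d)",
                    projection.value, seed, attempt)
    raise sim.SimulationError(
        f"no cell passing the tuning gate for {projection.value} seed {seed}")


def _invitro_cell_metrics(cell: Cell, cfg: ExperimentConfig,
                          block: dict | None = None) -> analysis.ReboundMetrics:
    target = apply = cell
    if block:
        apply = sim.apply_pharmacology(cell, block)
    tr = sim.rebound_protocol(apply, target_vmin_mV=cfg.target_vmin_mV,
                              step_duration_ms=cfg.step_duration_ms)
    return analysis.rebound_metrics(tr)


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    if config.experiment == "fig7_invitro":
        rows = []
        for proj in config.projections:
            pc = ProjectionClass(proj)
            for s in _cell_seeds(config.seed, config.effective_n):
                cell = _sample_gated(pc, s, config)
                m = _invitro_cell_metrics(cell, config)
                row = m.to_dict()
                row.update(projection=proj, cell_seed=s)
                rows.append(row)
        df = pd.DataFrame(rows)
        files["cells"] = out / "invitro_cell_metrics.csv"
        df.to_csv(files["cells"], index=False)
        summary = df.groupby("projection")[
            ["rebound_delay_s", "r_isi_freq_1_hz", "sag_mV",
             "baseline_rate_hz"]].agg(["mean", "std"])
        files["summary"] = out / "invitro_summary.csv"
        summary.to_csv(files["summary"])

    elif config.experiment in _PHARMA_BLOCKS:
        block = _PHARMA_BLOCKS[config.experiment]
        rows = []
        for proj in config.projections:
            pc = ProjectionClass(proj)
            for s in _cell_seeds(config.seed, config.effective_n):
                cell = _sample_gated(pc, s, config)
                for cond, blk in (("control", None), ("block", block)):
                    m = _invitro_cell_metrics(cell, config, blk)
                    row = m.to_dict()
                    row.update(projection=proj, cell_seed=s, condition=cond)
                    rows.append(row)
        df = pd.DataFrame(rows)
        files["cells"] = out / f"{config.experiment}_metrics.csv"
        df.to_csv(files["cells"], index=False)

    elif config.experiment == "figS3_durations":
        pc = ProjectionClass(config.projections[0])
        s = _cell_seeds(config.seed, 1)[0]
        cell = _sample_gated(pc, s, config)
        df = duration_sweep(cell, config.durations_ms,
                            target_vmin_mV=config.target_vmin_mV)
        files["durations"] = out / "duration_sweep.csv"
        df.to_csv(files["durations"], index=False)

    elif config.experiment == "fig9_invivo":
        sig_rows = []
        for proj in config.projections:
            res = invivo.run_population_rebound(
                proj, n_cells=config.effective_n, seed=config.seed,
                step_ms=config.step_duration_ms,
                target_vmin_mV=config.target_vmin_mV)
            files[f"metrics_{proj}"] = out / f"invivo_metrics_{proj}.csv"
            res.to_frame().to_csv(files[f"metrics_{proj}"], index=False)
            edges, counts = res.psth()
            files[f"psth_{proj}"] = out / f"invivo_psth_{proj}.csv"
            pd.DataFrame({"bin_start_ms": edges[:-1], "count": counts}).to_csv(
                files[f"psth_{proj}"], index=False)
            raster = pd.DataFrame(
                [(k, t) for k, ts in enumerate(res.spike_times_ms) for t in ts],
                columns=["cell", "time_ms"])
            files[f"raster_{proj}"] = out / f"invivo_raster_{proj}.csv"
            raster.to_csv(files[f"raster_{proj}"], index=False)
            if res.active_mask.sum() >= 2:
                stats = invivo.post_release_significance(res, seed=config.seed)
                stats["projection"] = proj
                sig_rows.append(stats)
        if sig_rows:
            files["significance"] = out / "invivo_significance.csv"
            pd.DataFrame(sig_rows).to_csv(files["significance"], index=False)

    manifest = _write_manifest(config, files, out)
    return manifest


def duration_sweep(cell: Cell, durations_ms: Sequence[float],
                   target_vmin_mV: float = -80.0) -> pd.DataFrame:
    """Rebound delay and first rebound frequency versus the duration of the
    preceding hyperpolarization (one settled state shared across steps)."""
    state = sim.settle(cell)
    rows = []
    for dur in durations_ms:
        tr = sim.rebound_protocol(cell, target_vmin_mV=target_vmin_mV,
                                  step_duration_ms=float(dur), state=state)
        m = analysis.rebound_metrics(tr)
        rows.append({
            "duration_ms": dur,
            "rebound_delay_s": m.rebound_delay_s,
            "r_isi_freq_1_hz": (m.r_isi_freq_hz[0] if m.r_isi_freq_hz else None),
            "vmin_mV": m.vmin_mV,
        })
    return pd.DataFrame(rows)


def fit_saturating_exponential(durations_ms: np.ndarray,
                               values: np.ndarray) -> dict:
    """Least-squares fit of y = a*(1 - exp(-t/tau)) + c."""
    from scipy.optimize import curve_fit

    def f(t, a, tau, c):
        return a * (1 - np.exp(-t / tau)) + c

    p0 = (values.max() - values.min(), np.median(durations_ms), values.min())
    popt, _ = curve_fit(f, durations_ms, values, p0=p0, maxfev=20000)
    resid = values - f(durations_ms, *popt)
    ss_tot = np.sum((values - values.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return {"amplitude": popt[0], "tau_ms": popt[1], "offset": popt[2],
            "r_squared": float(r2)}


def _write_manifest(config: ExperimentConfig, files: dict[str, Path],
                    out: Path) -> dict:
    from nigra import __version__

    entries = {}
    for key, path in files.items():
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries[key] = {"path": str(path), "sha256": digest}
    manifest = {
        "experiment": config.experiment,
        "config": {**asdict(config),
                   "projections": list(config.projections),
                   "durations_ms": list(config.durations_ms)},
        "version": __version__,
        "outputs": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
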