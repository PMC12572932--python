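"""Balanced-state environment: Poisson schedule statistics, exclusion rule
and the paired post-release test."""

import numpy as np
import pytest
from scipy import stats

from nigra import invivo
from nigra import simulate as sim
from nigra.analysis import ReboundMetrics
from nigra.cell import make_cell
from nigra.invivo import (BalancedStateConfig, PopulationResult,
                          generate_synaptic_schedule,
                          post_release_significance)
from nigra.simulate import StimulusProtocol


@pytest.fixture(scope="module")
def vivo_cell():
    return make_cell("DLS", 1, in_vivo=True)


@pytest.fixture(scope="module")
def long_schedule(vivo_cell):
    cfg = BalancedStateConfig(seed=7)
    # ~1e5 events per stream at the 5 ms mean interval
    return generate_synaptic_schedule(vivo_cell, cfg, 500_000.0)


def test_event_count_within_3sd(long_schedule):
    for kind in ("E", "I"):
        n = int((long_schedule["kind"] == kind).sum())
        expect = 500_000.0 / 5.0
        assert abs(n - expect) <= 3 * np.sqrt(expect)


def test_interval_statistics_poisson(long_schedule):
    for kind in ("E", "I"):
        t = long_schedule.loc[long_schedule["kind"] == kind, "time_ms"].to_numpy()
        isis = np.diff(t)
        assert isis.mean() == pytest.approx(5.0, rel=0.02)
        cv = isis.std() / isis.mean()
        assert cv == pytest.approx(1.0, abs=0.02)


def test_ais_never_receives_events(vivo_cell, long_schedule):
    assert not np.any(long_schedule["compartment"].to_numpy()
                      == vivo_cell.ais_idx)


def test_compartment_targeting_proportional_to_area(vivo_cell, long_schedule):
    """Multinomial goodness of fit of per-compartment event counts against
    the surface-area distribution."""
    counts = np.bincount(long_schedule["compartment"], minlength=vivo_cell.n)
    areas = vivo_cell.area_cm2.copy()
    areas[vivo_cell.ais_idx] = 0.0
    p = areas / areas.sum()
    keep = p > 0
    chi2, pval = stats.chisquare(counts[keep],
                                 f_exp=p[keep] * counts.sum())
    assert pval > 1e-3


def test_streams_statistically_independent(long_schedule):
    """Lag-0 cross-correlation of 50 ms binned E and I counts ~ 0."""
    edges = np.arange(0, 500_000.0 + 50, 50.0)
    e = np.histogram(long_schedule.loc[long_schedule.kind == "E", "time_ms"],
                     bins=edges)[0]
    i = np.histogram(long_schedule.loc[long_schedule.kind == "I", "time_ms"],
                     bins=edges)[0]
    r = np.corrcoef(e, i)[0, 1]
    assert abs(r) < 3.0 / np.sqrt(len(e))


def test_zero_rate_schedule_empty(vivo_cell):
    cfg = BalancedStateConfig(g_e_nS=0.0, g_i_nS=0.0)
    assert len(generate_synaptic_schedule(vivo_cell, cfg, 1000.0)) == 0


def test_schedule_deterministic_per_seed(vivo_cell):
    cfg = BalancedStateConfig(seed=3)
    a = generate_synaptic_schedule(vivo_cell, cfg, 5000.0)
    b = generate_synaptic_schedule(vivo_cell, cfg, 5000.0)
    assert a.equals(b)


def test_zero_amplitude_environment_is_identity(vivo_cell):
    """With zero synaptic amplitudes the cell keeps its pacemaker rate."""
    from nigra import analysis

    state = sim.settle(vivo_cell, duration_ms=3000.0)
    cfg0 = BalancedStateConfig(g_e_nS=0.0, g_i_nS=0.0)
    ev = generate_synaptic_schedule(vivo_cell, cfg0, 4000.0)
    tr = sim.integrate(vivo_cell, [],
                       sim.SimulationConfig(duration_ms=4000.0,
                                            record_sites=(vivo_cell.soma_idx,)),
                       state=state.copy(), events=ev)
    tr0 = sim.integrate(vivo_cell, [],
                        sim.SimulationConfig(duration_ms=4000.0,
                                             record_sites=(vivo_cell.soma_idx,)),
                        state=state.copy())
    r = analysis.detect_spikes_in_vitro(tr, filter_first=False)
    r0 = analysis.detect_spikes_in_vitro(tr0, filter_first=False)
    assert len(r) == len(r0)
    assert np.allclose(r.times_ms, r0.times_ms, atol=0.5)


# ---------------------------------------------------------------------------
# population containers and significance


def _fake_population(rates_pre, rates_post, seed=0, dur=10_000.0,
                     onset=5000.0, step=2000.0):
    rng = np.random.default_rng(seed)
    spikes = []
    for rp, rq in zip(rates_pre, rates_post):
        pre = rng.uniform(0, onset, size=rng.poisson(rp * onset / 1e3))
        post0 = onset + step
        post = post0 + rng.uniform(0, 1000.0, size=rng.poisson(rq))
        tail = post0 + 1000.0 + rng.uniform(0, dur - post0 - 1000.0,
                                            size=rng.poisson(rp))
        spikes.append(np.sort(np.concatenate([pre, post, tail])))
    proto = StimulusProtocol(amplitude_pA=-100.0, onset_ms=onset,
                             duration_ms=step)
    metrics = [ReboundMetrics(-80.0, None, [], False, 5.0, rp, 1.0)
               for rp in rates_pre]
    return PopulationResult(projection="DLS", spike_times_ms=spikes,
                            metrics=metrics,
                            cell_seeds=list(range(len(spikes))),
                            protocol=proto, baseline_window_ms=(0.0, onset),
                            duration_ms=dur)


def test_psth_counts_match_raster_totals():
    pop = _fake_population([3.0] * 10, [3.0] * 10)
    edges, counts = pop.psth(active_only=False)
    assert counts.sum() == sum(len(t) for t in pop.spike_times_ms)
    assert np.allclose(np.diff(edges), 100.0)


def test_exclusion_rule_is_zero_baseline_spikes():
    pop = _fake_population([3.0, 3.0], [3.0, 3.0])
    pop.spike_times_ms[1] = pop.spike_times_ms[1][
        pop.spike_times_ms[1] >= pop.baseline_window_ms[1]]
    assert list(pop.active_mask) == [True, False]


def test_significance_null_case_not_rejected():
    """Identical pre/post rates by construction: rejection at 0.01 happens
    at roughly the nominal rate (checked over 20 null populations)."""
    rejections = 0
    for s in range(20):
        pop = _fake_population([4.0] * 12, [4.0] * 12, seed=s)
        out = post_release_significance(pop, seed=s, n_permutations=2000)
        rejections += out["p_value"] < 0.01
    assert rejections <= 2


def test_significance_detects_doubled_post_rate():
    pop = _fake_population([4.0] * 30, [8.0] * 30, seed=1)
    out = post_release_significance(pop, seed=1)
    assert out["p_value"] < 0.01
    assert out["direction"] == "increase"


def test_significance_needs_two_active_cells():
    pop = _fake_population([3.0], [3.0])
    with pytest.raises(ValueError):
        post_release_significance(pop)


def test_population_frame_schema():
    pop = _fake_population([3.0] * 3, [3.0] * 3)
    df = pop.to_frame()
    assert {"cell_seed", "rebound_delay_s", "baseline_rate_hz",
            "active"}.issubset(df.columns)
    assert len(df) == 3
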