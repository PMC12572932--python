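# Methods

This note records the model, the numerical scheme, the calibration choices
and their rationale, and what the tests do and do not establish.

## Cell model

**Morphology.** All three projection classes share one simplified tree: a
cylindrical soma (25 × 25 µm), two primary dendrites (2 µm diameter) that
split 75–150 µm from the soma (default 100 µm) into two 250 µm distal
branches tapering to 1 µm, a 50 µm side branch at 50 µm on one primary (this
side branch plus the primary segment proximal to it are tagged as the
axon-bearing dendrite, ABD), and a 30 × 1.5 µm axon initial segment (AIS) on
the side-branch tip.  The dendritic tree is discretized into exactly 114
electrical segments, allocated to branches proportionally to length (floor,
then remainder to the longest branches) — deterministic and close to uniform
spatial resolution.  Compartment coordinates are path distances from the
soma center; no 3D embedding.  Axial resistivity is 200 Ω·cm; axial coupling
between segment centers uses the standard two-half-cylinder formula.
Surface areas are lateral cylinder areas (π·d·L), including the soma: the
soma enters the model only through its area and the choice of cylinder vs
sphere is absorbed by its configurable dimensions.

**Membrane mechanisms.**  C_m = 1 µF/cm².  Currents are ohmic,
g·o·(V − E), with E_Na = +60, E_K = −90, E_HCN = −30 and a constant calcium
driving force E_Ca = +60 mV (a GHK form was considered and not needed for
the reproduced phenomena).  The gate kinetics are Boltzmann steady states
with constant or bell-shaped time constants; every constant lives in
`src/nigra/data/channel_params.yaml` (versioned; loaders reject unknown
keys).  The sodium channel is a reduced 3-state Markov scheme (closed,
open, inactivated) with voltage-dependent transitions C↔O, O→I, I→C and
C→I; its occupancies are advanced by an exact implicit-Euler solve of the
master equation, which preserves the occupancy sum to round-off and is
unconditionally stable.

**Calcium handling.**  Two pools per compartment, both first-order:
a *microdomain* read exclusively by SK, fed by the N-type current plus a
fraction *f* of the T-type current (L-type contributes nothing — it is
purely electrogenic), with a per-cell time constant τ_micro and an
influx-to-concentration factor derived from a 0.15 µm shell; and a *bulk*
pool (1 µm shell, τ 200 ms) fed by all calcium currents, kept for
bookkeeping.  SK activation is Hill with K_D = 0.35 µM and coefficient 4.

**Spatial rules.**  T-type conductance is zero within 150 µm of the soma and
uniform at the sampled density beyond; K_v4.3 is 5× denser in the soma than
in dendrites; HCN is 3× elevated on ABD compartments; spiking gNa and gK_DR
are 5× in the AIS and attenuate linearly with path distance to 20% of the
somatic density at the most distal segment.  The 3× ABD factor and the
linear 20% ramp are declared defaults — the elevation/attenuation are
qualitative constraints without published profiles.

**Class parameters.**  Sampled ranges (µS/cm², ms): leak split gNa_L/gK_L
(single shared draw, sum fixed at 10.5 for DLS and 11 for DMS/lNAcc),
τ_Kv4 (DLS 25–50, DMS 75–125, lNAcc 60–100), dendritic gK_v4 (135–225 vs
225–360), distal gCaT (DLS 350–450 vs 150–250), gSK (75–150 vs 100–200),
gHCN (15–20), gGIRK (20 in vitro; uniform 10–30 in vivo).  The coupling
fraction *f* and τ_micro are calibration choices (below).  Spiking and AHP
densities (gNa 15 000, gK_DR 3500, gCaL 155, gCaN 60, gM 50, gERG 150
µS/cm²) were tuned by grid search against the action-potential criteria and
then frozen in the parameter file; they are identical across classes.

## Numerics

Staggered scheme at dt = 0.025 ms: gates by exponential Euler using voltage
lookup tables (0.05 mV grid, linear interpolation), Markov occupancies by
the implicit 3×3 solve, calcium by exponential Euler, then voltage by a
backward-Euler solve of the cable equation on the tree (Hines elimination).
An explicit exponential-Euler voltage update is available for cross-checks.
Recording is decimated to 20 kHz to match experimental sampling.  Every
simulation starts from a 5 s unrecorded settling run (3–4 s in the scaled
test protocols) so pacemakers reach their limit cycle.  Divergence
(|V| > 200 mV) aborts with a structured error.  The declared convergence
contract — halving dt changes subthreshold voltage samples by < 0.1 mV — is
tested on passive and small active cables; pointwise agreement through spike
upstrokes is not claimed (spike-time jitter dominates there).

Synapses are bi-exponential conductances (AMPA 0.2/2 ms, NMDA 2/80 ms with
sigmoidal Mg block at 1 mM and an NMDA:AMPA peak ratio of 0.5, GABA_A
0.5/8 ms; reversals 0 and −65 mV), implemented with rise/decay state pairs
so arbitrary event schedules cost O(1) per event.

## Calibration choices and their rationale

The published tuning targets are: AP peak between +10 and +30 mV, threshold
near −40 mV (±3 mV declared), width 2 ms at threshold (±0.5 ms declared),
AIS initiation; DLS pacemaking near 3.4 Hz with rebound delay ≈ 0.085 s at
V_min = −80 mV and a first rebound frequency about twice baseline; DMS and
lNAcc as slow ramps (delays ≈ 0.4–0.6 s, rebound within the baseline band);
SK block raising the maximal rebound frequency roughly threefold while slow
firing persists; GIRK suppressing rate and delaying the rebound.  Reaching
all of these simultaneously fixed several choices:

- **CaT voltage dependence** (activation V½ −55, k 5; inactivation V½ −80,
  k −4, τ up to ~0.4 s near −80 mV): steep inactivation keeps the T-channel
  silent at pacemaking potentials — a tonic T window current combined with
  the CaT→SK feedback otherwise locks the cell at a subthreshold fixed
  point — while 2 s at −80 mV de-inactivates enough channels to drive the
  rebound.  The slow inactivation time constant at −80 mV also produces the
  observed saturating growth of rebound strength with step duration.
- **Coupling fraction f and τ_micro**: DLS f ∈ 0.08–0.16 with τ_micro
  5–10 ms; DMS/lNAcc f ∈ 0.5–0.9 with τ_micro 15–30 ms.  With the Hill
  coefficient of 4, SK acts nearly as a switch on the T-current: couplings
  above ~0.2 abolish the DLS burst outright rather than merely restraining
  its gain.  The weaker, faster DLS microdomain expresses the reduced
  calcium-channel/SK coupling that distinguishes this class.
- **KDR deactivation** is slowed below −50 mV (τ ~5–7 ms): the resulting
  fast AHP spaces spikes inside the rebound burst.  Without it, removing SK
  yields 100 Hz spikelet doublets instead of the reported graded 20–30 Hz
  bursts.
- **CaL (Ca_v1.3) slow inactivation** (V½ −45 mV, τ 300 ms): the L-type
  window current is the main subthreshold pacemaker drive; without
  inactivation, blocking SK ends in depolarization block instead of the
  ERG-limited slow firing the channel repertoire is supposed to maintain.
- **GIRK at 20 µS/cm²** roughly triples the resting conductance, so
  pacemaking under the in-vitro condition is driven by the L-type window
  plus HCN rather than by the leak reversal alone.

**Pharmacology protocol.**  Blocks scale maximal conductances by (1 − block
fraction); full block by default.  The hyperpolarizing amplitude is titrated
under control (bisection to V_min = −80 ± 0.5 mV at the soma) and reused for
the blocked condition: SK block makes the spontaneous after-burst minima
cross −80 mV, which defeats per-condition titration, and SK is closed during
the hyperpolarization itself, so the control amplitude reaches the same
minimum.

## Balanced state (in vivo environment)

Two independent Poisson event streams (mean inter-event interval 5 ms each)
deliver glutamate (AMPA+NMDA) and GABA_A events to compartments drawn with
probability proportional to surface area, never to the AIS; amplitudes are
identical across compartments.  Tonic GIRK (drawn 10–30 µS/cm²) stands in
for basal D2/GABA_B tone.  Default event amplitudes (E 0.7 nS, I 8 nS) were
found by the included coordinate-descent calibrator against three targets:
population mean rate inside the observed 1–8 Hz band, in-vitro/in-vivo input
resistance ratio ≈ 2 (measured as the V–I slope of hyperpolarizing steps
during the barrage), and increased ISI irregularity.  Inhibition must be
strong because GABA_A reverses at −65 mV, close to the operating point, so
it acts mostly by shunting.

The population rebound experiment samples per-cell parameters and noise from
a split seed stream, titrates the step per cell on a 1 kHz-filtered probe
trace (±1 mV), and excludes cells with zero spikes during the balanced-state
baseline — exactly the published exclusion rule.  The post-release test is a
paired one-sided sign-flip permutation test (10⁴ permutations, fixed seed)
on per-cell rate differences between the 1 s window after release and the
balanced-state baseline; the original analysis does not name its test, and
the paired permutation makes the fewest distributional assumptions.
Population sizes default to 60 (the figure-level n; the methods text of the
source model mentions 30) and are scaled down in tests and the acceptance
script (5–6 cells, 8–30 s windows) to keep desk-scale runtimes; the test
suite documents each scaled size.

## Analysis pipeline

1 kHz zero-phase low-pass (4th-order Butterworth, `sosfiltfilt`); central
difference derivative; in-vitro spikes at the first sample of an upstroke
with dV/dt ≥ 10 mV/ms (one spike per suprathreshold excursion — the detector
is refractory until V falls back below that spike's threshold voltage);
in-vivo spikes additionally require, within 3 ms, a minimum dV/dt below
−5 mV/ms and a peak more than 10 mV above the whole-trace mean.  Rebound
delay is step offset to first post-offset spike peak (undefined — flagged,
not a sentinel — if none within a declared 5 s horizon); rebound frequencies
are the reciprocals of the first six post-offset ISIs; sag is the steady
state (mean of the final 25% of the step — the declared window) minus the
in-step minimum; input resistance is the least-squares V–I slope over ≥ 2
step levels; bursts open at the first of two spikes with ISI < 80 ms and
close before the first ISI > 160 ms.  Model traces are analyzed unfiltered
(they are noise-free; the filter is for recorded or surrogate data).

## What the synthetic data do and do not show

`nigra.surrogate` builds 20 kHz traces from stereotyped spline action
potentials, an exact-minimum step response with a planted sag, a scheduled
rebound burst and white Gaussian noise.  It shares no code with the
simulator, so round-trip tests (planted value in → metric out) validate the
analysis pipeline independently.  The surrogates emulate only the features
the metrics read: they have no biophysical subthreshold dynamics, no
spike-shape variability, and stationary noise, so passing them shows metric
correctness, not robustness to every artifact of real recordings.
Conversely, the simulator is validated against closed forms (RC step,
calcium fixed points, Markov null-space eigenvectors), conservation laws
(Kirchhoff residual on a dense re-assembly, occupancy sums) and oracle
re-implementations (burst scan, path-distance walks), not against the
original laboratory recordings, which are not available.

## Known limitations

- Gate kinetics are standard formulations tuned to the published criteria,
  not transcriptions of the original model code; quantities the tuning
  targets do not constrain (e.g., exact sag amplitudes, DMS/lNAcc rebound
  delay spread) match the published values only approximately.
- No temperature dependence, no stochastic gating outside the (deterministic)
  Markov Na scheme, no intracellular buffer chemistry, no voltage clamp.
- The in-vivo calibration targets population means; individual sampled cells
  can fall outside the 1–8 Hz band or the ratio-2 input-resistance target.
- A small fraction of sampled parameter sets (~1 in 8 for DLS) fail to
  pacemake; population experiments gate on the tuning criteria and resample,
  mirroring the original tuning procedure.
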