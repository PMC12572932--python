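# Canonical channel kinetics and fixed densities for the DA SN models.
# version bumps whenever any constant changes. Loaders reject unknown keys.
#
# Gate kinetics are standard Boltzmann/bell formulations tuned so that the
# assembled cells meet the spiking criteria (AP peak +10..+30 mV, threshold
# near -40 mV, width ~2 ms at threshold, AIS initiation) and the rebound
# phenotypes of the three projection classes.
#
# Units: voltages mV, times ms, densities uS/cm^2, concentrations uM.
version: 4

membrane:
  capacitance_uF_cm2: 1.0

reversal_mV:
  na: 60.0
  k: -90.0
  h: -30.0     # HCN mixed-cation reversal
  ca: 60.0     # constant ohmic Ca driving force (GHK not used)

# Hodgkin-Huxley-style gates.  xinf(V) = 1/(1+exp(-(V-vhalf)/k)) (k<0 for
# inactivation gates); tau(V) = tau_min + tau_amp/(exp((V-vt)/ka) + exp(-(V-vt)/kb)),
# or a constant when tau_amp is 0.
gates:
  kdr_n:  {vhalf: -35.0, k: 6.0,  power: 3, tau_min: 0.5, tau_amp: 6.5,  vt: -50.0, ka: 8.0,  kb: 20.0}
  ka_a:   {vhalf: -45.0, k: 10.0, power: 2, tau_min: 1.5, tau_amp: 0.0,  vt: 0.0,   ka: 1.0,  kb: 1.0}
  # ka_b tau is the per-cell sampled Kv4 inactivation time constant; tau fields unused
  ka_b:   {vhalf: -78.0, k: -6.0, power: 1, tau_min: 50.0, tau_amp: 0.0, vt: 0.0,   ka: 1.0,  kb: 1.0}
  hcn_h:  {vhalf: -88.0, k: -6.5, power: 1, tau_min: 50.0, tau_amp: 250.0, vt: -85.0, ka: 14.0, kb: 14.0}
  cat_m:  {vhalf: -55.0, k: 5.0,  power: 2, tau_min: 10.0, tau_amp: 12.0, vt: -60.0, ka: 12.0, kb: 12.0}
  cat_h:  {vhalf: -80.0, k: -4.0, power: 1, tau_min: 15.0, tau_amp: 400.0, vt: -74.0, ka: 12.0, kb: 18.0}
  cal_m:  {vhalf: -42.0, k: 5.0,  power: 1, tau_min: 1.0, tau_amp: 0.0,  vt: 0.0,   ka: 1.0,  kb: 1.0}
  cal_h:  {vhalf: -45.0, k: -6.0, power: 1, tau_min: 300.0, tau_amp: 0.0, vt: 0.0,  ka: 1.0,  kb: 1.0}
  can_m:  {vhalf: -18.0, k: 7.0,  power: 2, tau_min: 0.8, tau_amp: 0.0,  vt: 0.0,   ka: 1.0,  kb: 1.0}
  m_m:    {vhalf: -30.0, k: 9.0,  power: 1, tau_min: 80.0, tau_amp: 0.0, vt: 0.0,   ka: 1.0,  kb: 1.0}
  erg_o:  {vhalf: -42.0, k: 6.0,  power: 1, tau_min: 300.0, tau_amp: 0.0, vt: 0.0,  ka: 1.0,  kb: 1.0}

# Reduced 3-state Markov sodium scheme (closed C, open O, inactivated I).
# Rates r/(1+exp(-(V-vhalf)/k)) in 1/ms; k<0 gives rates that grow with
# hyperpolarization (deactivation, recovery).
markov_na:
  a_co: {r: 10.0, vhalf: -23.0, k: 4.5}   # activation C->O
  b_oc: {r: 10.0, vhalf: -35.0, k: -4.5}  # deactivation O->C
  k_oi: {r: 3.0,  vhalf: -15.0, k: 6.0}   # open-state inactivation O->I
  k_ic: {r: 0.30, vhalf: -75.0, k: -7.0}  # recovery I->C
  k_ci: {r: 0.15, vhalf: -50.0, k: 6.0}   # closed-state inactivation C->I

sk:
  kd_uM: 0.35
  hill: 4.0

calcium:
  floor_uM: 0.05
  micro_shell_depth_um: 0.15   # sets the influx-to-concentration factor of the SK microdomain
  bulk_shell_depth_um: 1.0
  bulk_tau_ms: 200.0

# Spiking densities tuned (grid search) to the AP criteria, then frozen here;
# they are not part of the sampled per-class ranges.
tuned_densities_uS_cm2:
  gna: 15000.0
  gkdr: 3500.0
  gcal: 155.0
  gcan: 60.0
  gm: 50.0
  gerg: 150.0

spatial:
  ais_spiking_factor: 5.0      # gNa and gKDR multiplied by 5 in the AIS
  distal_spiking_fraction: 0.2 # linear ramp of gNa/gKDR to 20% at the most distal segment
  abd_hcn_factor: 3.0          # HCN elevation on ABD compartments
  cat_min_distance_um: 150.0   # no T-type conductance within 150 um of the soma
  kv4_soma_dendrite_ratio: 5.0

synapse:
  ampa: {tau_rise_ms: 0.2, tau_decay_ms: 2.0, e_mV: 0.0}
  nmda: {tau_rise_ms: 2.0, tau_decay_ms: 80.0, e_mV: 0.0, mg_mM: 1.0}
  gaba: {tau_rise_ms: 0.5, tau_decay_ms: 8.0, e_mV: -65.0}
  nmda_ampa_ratio: 0.5
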