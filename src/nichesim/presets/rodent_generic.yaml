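name: rodent_generic
params:
  switch:
    Q_max: 100.0
    theta: 10.0
    sigma: 3.0
    nu_vm: -2.1
    nu_mv: -1.8
    nu_vh: 1.0
    A_m: 1.3
    tau_v: 10.0
    tau_m: 10.0
    noise_sd: 0.2
  homeostat:
    chi: 2.0
    mu: 4.4
  pacemaker:
    tau_c: 24.2
    vdp_coeffs:
      gamma: 0.13
      f: 0.99669
      q: 0.3333333333333333
      k: 0.55
    rho_np: 0.032
    np_wake: 0.3333333333333333
    np_sleep: -0.6666666666666666
  photic:
    alpha_0: 0.0016666666666666668
    p: 0.5
    I_0: 9500.0
    I_1: 100.0
    beta: 0.00011666666666666667
    G: 2220.0
    b: 0.4
    eye_closure_factor: 0.0
  relay:
    nu_spz: -1.0
    c_offset: 1.0
    g_dmh_vlpo: 8.0
    g_dmh_lha: 0.0
    m_mask: 0.0
    scn_gain: 1.0
    masking_mode: photoreceptor
    I_mask_ref: 100.0
  wake_threshold: 1.0
provenance:
  switch: nominal (antecedent sleep/wake switch + circadian pacemaker lineage)
  pacemaker: nominal (antecedent sleep/wake switch + circadian pacemaker lineage)
  photic: nominal (antecedent sleep/wake switch + circadian pacemaker lineage)
  homeostat.chi: fitted (polyphasic rodent bout structure, tens of wake bouts per
    day)
  relay.c_offset: fitted (daily wake duration)
  relay.g_dmh_vlpo: fitted (strength of circadian day/night modulation of the wake
    duty cycle)
  relay.nu_spz: nocturnal (-1) by default; swept in experiments
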