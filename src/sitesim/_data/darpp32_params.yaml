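# SYNTHETIC parameterisation of the built-in DARPP-32 network.
#
# The published reaction system carries its rate constants, initial
# concentrations and stimulus protocol inside the curated SBML file
# (BioModels BIOMD0000000153); translating that file with `sitesim translate`
# recovers them.  This packaged table instead provides order-of-magnitude
# defaults chosen once so the built-in model is runnable self-contained:
# weak (micromolar-range) bindings, second-scale catalysis, DARPP-32 in
# excess of its interactors.  See docs/methods.md for the reasoning.
volume_litres: 1.0e-15

initial_copies:
  D: 5000        # DARPP-32 exceeds the pools of all its interactors
  R2C2: 600      # PKA holoenzyme (catalytic subunits start bound)
  PP2B: 1000
  CDK5: 600
  CK1: 600
  PP2A: 1000
  PP2C: 600
  PDE: 1000
  cAMP: 0
  Ca: 0

rates:              # stochastic units: /s (unary), /s per pair (binary+)
  # DARPP-32 phosphorylation component: enzyme bind / catalyse / unbind
  pka_d_bind: 1.0e-4
  pka_d_cat: 2.0
  pka_d_unbind: 0.5
  pp2b_d_bind: 1.0e-4
  pp2b_d_cat: 2.0
  pp2b_d_unbind: 0.5
  cdk5_d_bind: 1.0e-4
  cdk5_d_cat: 1.0
  cdk5_d_unbind: 0.5
  ck1_d_bind: 1.0e-4
  ck1_d_cat: 1.0
  ck1_d_unbind: 0.5
  pp2a_d_bind: 1.0e-4
  pp2a_d_cat: 1.5
  pp2a_d_unbind: 0.5
  pp2c_d_bind: 1.0e-4
  pp2c_d_cat: 1.5
  pp2c_d_unbind: 0.5
  # CK1 phosphorylation component
  ck1_auto: 0.02
  pp2b_ck1_bind: 1.0e-4
  pp2b_ck1_cat: 1.0
  pp2b_ck1_unbind: 0.5
  # PDE phosphorylation component
  pka_pde_bind: 1.0e-4
  pka_pde_cat: 1.0
  pka_pde_unbind: 0.5
  pde_dephos: 0.05
  # PP2A phosphorylation component
  pka_pp2a_bind: 1.0e-4
  pka_pp2a_cat: 1.0
  pka_pp2a_unbind: 0.5
  pp2a_dephos: 0.05
  # PP2B activation (two reversible two-ion calcium steps)
  pp2b_ca_on1: 1.0e-6
  pp2b_ca_off1: 1.0
  pp2b_ca_on2: 2.0e-6
  pp2b_ca_off2: 0.5
  # PKA activation (two reversible two-molecule cAMP steps + subunit release)
  r2c2_camp_on1: 1.0e-6
  r2c2_camp_off1: 1.0
  r2c2_camp_on2: 2.0e-6
  r2c2_camp_off2: 0.5
  pka_release: 5.0
  pka_rebind: 1.0e-4
  # cAMP & Ca degradation component
  camp_synth: 2.0
  camp_deg_basal: 0.02
  camp_deg_pde: 1.0e-5
  camp_deg_pde_p: 5.0e-5
  ca_leak: 2.0
  ca_efflux: 0.05
  # PP2A activation by Ca component
  pp2a_ca_bind: 1.0e-5
  pp2a_ca_bind_p: 2.0e-5
  pp2a_ca_unbind: 0.5

# Stimulus protocol: one cAMP pulse followed by a train of 20 calcium spikes
# (21 timed events in total).
stimuli:
  camp_pulse:
    time: 100.0
    copies: 10000
  ca_spikes:
    start: 300.0
    interval: 2.0
    count: 20
    copies: 5000
t_end: 800.0
record_dt: 1.0
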