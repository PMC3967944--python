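# Cross-model parameter name mapping for the consensus-rank analysis.
# version 1
#
# Keys: model id -> {model-local parameter name: shared name}.
# Parameters not listed keep their local names.  The shared vocabulary is
# the 14-parameter subset common to most models (I_Ks magnitude and gating,
# I_CaL magnitude/gating/voltage-dependence, I_Kr, I_to, I_Na, I_K1, the
# Na+/K+ pump, Na+/Ca2+ exchange and SERCA).
LR91:
  G_si: G_CaL     # slow inward current is the model's L-type pathway
  p_d: p_d
  p_f: p_f        # I_si inactivation gate, analogous to I_CaL f-gate
  p_x: p_xs       # the composite delayed rectifier is dominated by slow kinetics
  V_x: V_xs
  G_K: G_Ks
LR09:
  p_xs1: p_xs     # primary (fast) I_Ks activation gate
  K_pCa: K_pCa
TP06-epi: &tp06
  V_a_to: V_a_to
TP06-mid: *tp06
TP06-endo: *tp06
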