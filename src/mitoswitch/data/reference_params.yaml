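# Reference parameter set for the mitotic-arrest Bcl-2 network simulations.
# Units: concentrations in nM, time in seconds.
initial_conditions:
  B_oligomers: 0.0      # every Bak n-mer starts empty
  M: 3000.0             # free Mcl-1
  MB: 1000.0            # Mcl-1:Bak complex (sets total Bak)
  C_m: 1000.0           # mitochondrial cytochrome C
  C_c: 0.0              # cytoplasmic cytochrome C
parameters:
  sigma_M: 5.0e-6       # nM/s   Mcl-1 synthesis rate in mitosis
  delta_M: 1.3e-4       # 1/s    Mcl-1 degradation rate in mitosis
  alpha_M: 0.05         # 1/nM/s Bak/Mcl-1 association
  beta_M: 0.5           # 1/s    Bak/Mcl-1 dissociation
  gamma_m_model_I: 5000.0   # 1/nM/s CytC cytoplasmic translocation (tetramer pore)
  gamma_m_model_II: 0.5     # 1/nM/s CytC cytoplasmic translocation (256-mer pore)
  gamma_c: 0.5          # 1/s    CytC return to mitochondria
  alpha_12: 0.05        # 1/nM/s Bak dimerization
  beta_12: 500.0        # 1/s    Bak dimer dissociation
  alpha_24: 0.05        # 1/nM/s Bak tetramer association
  beta_24: 0.05         # 1/s    Bak tetramer dissociation
  alpha_other: 1.0      # 1/nM/s association, all higher oligomers
  beta_other: 1.0       # 1/s    dissociation, all higher oligomers
pore_size:
  model_I: 4
  model_II: 256
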