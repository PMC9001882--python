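# Default parameter set for the simplified merging-pathway model.
# Units: amounts in molecules per cell (X in cells), times in minutes.
# Values are package-calibrated defaults chosen to give a steady product
# level with partial post-perturbation recovery under the antithetic loop.
model: merging
params:
  K_S1: 2000.0        # molecules/min, constant precursor uptake
  kcat: 50.0          # 1/min
  Km_S1: 50000.0      # molecules
  Km_S2: 10000.0      # molecules
  S2_level: 10000.0   # molecules, externally set availability (= Km_S2)
  CN: 1.0             # copies
  a0: 0.0             # basal enzyme expression neglected in the simplified loop
  a1: 120.0           # molecules/min/copy, sigma-induced enzyme expression
  kd20: 200000.0      # molecules
  k_sigma: 500.0      # 1/min/copy, constitutive sigma expression
  gamma: 0.001        # 1/molecule/min, sigma/anti-sigma association
  k_asigma: 1000.0    # 1/min, anti-sigma expression strength
  kdp: 200.0          # molecules, product/TF dissociation
  TF_total: 50.0      # molecules, constitutive TF pool
  d_E: 0.02           # 1/min
  d_sigma: 0.01       # 1/min
  d_asigma: 0.01      # 1/min
  mu: 0.0075          # 1/min (mid of the tuning range)
  Xmax: 1.0e12        # cells
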