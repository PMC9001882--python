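# Default parameter set for the full naringenin production system.
# Units: amounts in molecules per cell (x in cells), volumes in litres,
# times in minutes.  Values are package-calibrated defaults targeting a
# ~1 g/L naringenin titer with an active antithetic loop (sigma above
# both the 4.5 uM floor and the anti-sigma level) and a visible
# sigma/CHS transient after a 60% malonyl-CoA reduction.
model: naringenin
params:
  metabolic:
    K_Lt: 3.0e7        # molecules/min, constant L-tyrosine influx
    kcat_TAL: 200.0
    kcat_4CL: 200.0
    kcat_CHS: 1000.0
    kcat_CHI: 200.0
    kcat_F3H: 50.0
    kcat_FLS: 50.0
    Km_Lt: 1.0e6
    Km_pC: 1.0e6
    Km_pA: 1.0e6
    Km_Ma: 13000.0     # ~= 20 uM, keeps the CHS step sensitive to malonyl-CoA
    Km_Nc: 1.0e6
    Km_N: 5.0e9        # keeps the readout drain linear in naringenin
    Km_Di: 1.0e6
    TAL: 2.0e5
    FCL: 2.0e5
    CHI: 2.0e5
    F3H: 1.0e4         # small readout drain (~2% of pathway flux)
    FLS: 1.0e4
    Ma_level: 13250.0  # molecules, ~20 uM basal malonyl-CoA availability
  biosensor:
    pQ: 5.0
    kQ: 2.0
    dmQ: 0.1386        # mRNA half-life ~5 min
    dQ: 0.01
    kdq: 100.0
    kdk: 80000.0
    CN: 5.0
  controller:
    p_sigma: 10.0
    k_sigma_n: 2.0
    dm_sigma: 0.1386
    d_sigma: 0.004
    alpha: 0.05        # promoter leakage fraction
    kdlux: 1.3e5
    kd2: 1.0e5
    kdc: 200.0         # sigma.anti-sigma complex dissociation constant
    k_minus_c: 1.0     # complex unbinding rate
    d_c: 0.001
    p_asigma: 10.0
    CN_asigma: 5.0
    k_asigma_n: 2.0
    dm_asigma: 0.1386
    d_asigma: 0.004
    CN: 5.0
  actuator:
    beta: 0.2          # constitutive fraction of CHS expression
    p_Hc: 20.0
    p_H: 5.0
    CN_h: 5.0
    k_H: 4.0
    dm_H: 0.1386
    d_H: 0.004
    kd20_n: 300.0
    kd_sigma: 6000.0
  ahl:
    p_R: 2.0
    k_R: 1.0
    dm_R: 0.1386
    d_R: 0.01
    D: 0.01            # 1/min, membrane diffusion
    Vcell: 1.1e-15     # L
    Vext: 1.0          # L
    d_A: 0.005
    d_Ae: 1.0e-6
    Ae_dose: 6.022e17  # molecules, ~1 uM AHL in the 1 L culture
  global:
    mu: 0.0116         # 1/min, doubling time ~60 min
    xmax: 1.0e12       # cells
    mw: 272.25         # g/mol, naringenin molecular weight
    Av: 6.02214076e23
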