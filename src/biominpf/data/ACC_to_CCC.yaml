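# Amorphous-precursor route: crystalline CC grows into a hydrated ACC
# layer deposited ahead of the front; the mother phase is the amorphous
# solid, with correspondingly slower diffusion and lower interface energies.
route: ACC_to_CCC
mother_phase: amorphous calcium carbonate
scales:
  gamma_A: 0.087        # J/m^2, CCC - ACC interface (Turnbull estimate)
  gamma_B: 0.068        # J/m^2, organic - ACC (gamma_A * T_B/T_A)
  delta: 4.15e-8        # m
  xi: 2.1e-6            # m
  v_m: 32.4e-6          # m^3/mol
  D_cM: 1.0e-15         # m^2/s, ion diffusion in ACC
  T_ref: 300.0          # K
thermo_pf1:             # same dimensionless driving force as the ion route
  T_r: 0.911
  T_rB: 0.786
  dg_A: -0.1184
  dg_B: 0.1554
mobilities_pf1:
  m_phi: 3.75
  m_cM: 1.0
  m_cC: 1.0e-14
  m_thetaM: 120.0
  m_thetaC: 1.2e-12     # 120 x 10^-14
mobilities_pf2:
  m_phi: 0.0144
  m_cM: 1.0
  m_cC: 1.0e-14
  m_thetaM: 12.0
  m_thetaC: 1.2e-13     # 12 x 10^-14
thermo_pf2:
  T_r: 0.720
  T_rA: 1.169
  T_rB: 1.286
  dg_A: -0.5802
  dg_B: -1.0477
  omega_M: 2.0510
  omega_C: 3.6335
numerics:
  dx: 6.25e-3
  dt_table: 4.75e-6
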