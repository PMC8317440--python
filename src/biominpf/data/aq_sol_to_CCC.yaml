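# Ion-by-ion route: crystalline CC grows directly from the aqueous
# (extrapallial-fluid) mother phase.  Dimensional materials data and the
# dimensionless mobilities/thermodynamics of the binary models.
route: aq_sol_to_CCC
mother_phase: aqueous solution
scales:
  gamma_A: 0.150        # J/m^2, CCC - aq. sol. interface
  gamma_B: 0.118        # J/m^2, organic - aq. sol. (gamma_A * T_B/T_A)
  delta: 4.15e-8        # m, interface thickness
  xi: 2.1e-6            # m, simulation length unit
  v_m: 26.7e-6          # m^3/mol
  D_cM: 1.0e-9          # m^2/s, ion diffusion in aqueous solution
  T_ref: 300.0          # K, anchor of the reduced-temperature scale
thermo_pf1:             # ideal-solution state (A = CC, B = organic)
  T_r: 0.911
  T_rB: 0.786
  dg_A: -0.1184
  dg_B: 0.1554
mobilities_pf1:
  m_phi: 3.75
  m_cM: 1.0
  m_cC: 1.0e-20
  m_thetaM: 120.0
  m_thetaC: 1.2e-18     # 120 x 10^-20
mobilities_pf2:
  m_phi: 0.0144
  m_cM: 1.0
  m_cC: 1.0e-20
  m_thetaM: 12.0
  m_thetaC: 1.2e-19     # 12 x 10^-20
thermo_pf2:             # regular-solution (eutectic) state, T_E-reduced
  T_r: 0.720
  T_rA: 1.169
  T_rB: 1.286
  dg_A: -0.5802
  dg_B: -1.0477
  omega_M: 2.0510
  omega_C: 3.6335
numerics:
  dx: 6.25e-3           # dimensionless grid spacing
  dt_table: 4.75e-6     # dimensionless reference time step
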