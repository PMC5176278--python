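# Printed (4-significant-figure) values of every model parameter, as
# tabulated in the source literature summary tables.  The package derives
# its working defaults from the underlying constants at full precision;
# this file is the printed record those derivations are validated against
# (relative tolerance 1e-3).
#
# Units: diffusivities cm^2/day; chi cm^5 g^-1 day^-1; production rates
# day^-1 (lam_E, lam_T, lam_P, lam_Ap additionally carry g/cm^3);
# degradation rates day^-1; concentrations g/cm^3.
D_Ec: 1.23e-4
D_m1: 0.13028
D_m2: 0.13028
D_C: 8.64e-7
D_N: 8.64e-7
chi: 3.0e-2            # invasion default; modelled range 3e-4 .. 3e-2
lam_E: 1.1741e-3
lam_M: 1.6499e-2
lam_A: 2.9422e-3
lam_MA: 0.5
lam_T: 8.4013e-4
lam_P: 2.3352e-4
lam_Ap: 4.4095e-3
lam_Ec: 9.81e-9
lam_m1: 8.626e-4
lam_m2: 4.313e-4
lam_C1: 0.6133
lam_C2: 0.3067
lam_N: 0.092           # tabulated; the text derivation gives 0.8*lam_C = 0.368
eps: 0.1
d_E: 0.8318
d_M: 0.6931
d_A: 0.6931
d_T: 0.3466
d_P: 22.1807
d_Ap: 2.7726
d_Ec: 21.8
d_m1: 0.5545
d_m2: 0.5545
d_C: 0.023
d_D: 0.414
d_N: 0.023             # tabulated; the text derivation gives 1.1*d_C = 0.0253
d_DN: 0.4554
# --- steady-state concentrations ---
steady.E_0: 7.0573e-4
steady.M_0: 8.4e-6
steady.P_30: 1.56e-6
steady.A_0: 9.362e-7
steady.T_0: 8.5050e-5
steady.P_0: 1.88e-7
steady.Ap_0: 2.84e-5
steady.E_C0: 3.6e-10
steady.m_10: 2.8e-13
steady.m_20: 1.4e-13
steady.C_0: 0.4
steady.N_0: 0.14
steady.C_M: 0.8
steady.gamma: 10.0
steady.theta: 0.6
# --- half-saturations (steady-state convention; miR half-saturations m_X0/5) ---
K_ME: 8.4e-6           # = M_0 (the lam_E = 2 d_E E_0 inversion requires it)
K_TM: 8.5050e-5
K_TA: 8.5050e-5
K_PA: 1.88e-7
K_mT: 0.56e-13
K_mP: 0.56e-13
K_m2: 0.28e-13
K_MA: 8.4e-6
K_C: 0.4
K_M: 8.4e-6
K_A: 9.362e-7
K_Ap: 2.84e-5
# --- rates never tabulated, closed from the steady-state conventions ---
lam_m1i: 3.8816e-12
lam_m2i: 1.9408e-12
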