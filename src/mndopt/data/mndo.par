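# Original MNDO parameters for H, C, N, O, F
# alpha in 1/angstrom; beta, U, E_isol in eV; zeta in 1/bohr
H alpha 2.544134
H beta_s -6.989064
H U_ss -11.906276
H zeta_s 1.331967
H E_isol -11.906276
C alpha 2.546380
C beta_s -18.985044
C beta_p -7.934122
C U_ss -52.279745
C U_pp -39.205558
C zeta_s 1.787537
C zeta_p 1.787537
C E_isol -120.500606
N alpha 2.861342
N beta_s -20.495758
N beta_p -20.495758
N U_ss -71.932122
N U_pp -57.172319
N zeta_s 2.255614
N zeta_p 2.255614
N E_isol -202.581201
O alpha 3.160604
O beta_s -32.688082
O beta_p -32.688082
O U_ss -99.643090
O U_pp -77.797472
O zeta_s 2.699905
O zeta_p 2.699905
O E_isol -317.868506
F alpha 3.419661
F beta_s -48.290460
F beta_p -36.508540
F U_ss -131.071548
F U_pp -105.782137
F zeta_s 2.848487
F zeta_p 2.848487
F E_isol -476.683781
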