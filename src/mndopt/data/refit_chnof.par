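# Refit MNDO-formalism parameters for C, H, N, O, F (local minimum of the
# weighted error function over a 1206-molecule CHNOF training set)
H alpha 2.993408
H beta_s -7.334656
H U_ss -10.314472
H zeta_s 1.124161
H E_isol -11.423363
C alpha 2.660499
C beta_s -13.719865
C beta_p -6.970837
C U_ss -47.292652
C U_pp -40.221274
C zeta_s 2.326858
C zeta_p 1.637021
C E_isol -112.533538
N alpha 3.021163
N beta_s -17.522551
N beta_p -15.550446
N U_ss -64.905273
N U_pp -57.638287
N zeta_s 2.914488
N zeta_p 2.126141
N E_isol -189.262258
O alpha 3.334554
O beta_s -73.616234
O beta_p -22.327739
O U_ss -94.106196
O U_pp -78.565181
O zeta_s 5.594470
O zeta_p 2.425014
O E_isol -309.024988
F alpha 3.590480
F beta_s -1753.340685
F beta_p -22.382738
F U_ss -107.380890
F U_pp -106.952003
F zeta_s 50.167806
F zeta_p 2.463961
F E_isol -434.411284
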