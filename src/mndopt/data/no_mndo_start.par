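# NO-MNDO parameter values for C, H, N, O (fluorine from original MNDO),
# used as an alternative optimization start
H alpha 2.687705
H beta_s -9.364858
H U_ss -10.880363
H zeta_s 1.061597
H E_isol -13.160122
C alpha 2.484460
C beta_s -16.208034
C beta_p -10.637421
C U_ss -50.189763
C U_pp -39.547267
C zeta_s 1.925428
C zeta_p 1.727933
C E_isol -119.594400
N alpha 2.658599
N beta_s -24.905520
N beta_p -21.291958
N U_ss -69.782951
N U_pp -56.981889
N zeta_s 2.351138
N zeta_p 1.951819
N E_isol -202.243600
O alpha 2.946645
O beta_s -35.477596
O beta_p -28.881783
O U_ss -96.705658
O U_pp -76.391762
O zeta_s 2.455548
O zeta_p 2.537964
O E_isol -304.341290
F alpha 3.419661
F beta_s -48.290466
F beta_p -36.508540
F U_ss -131.071550
F U_pp -105.782140
F zeta_s 2.848487
F zeta_p 2.848487
F E_isol -476.683780
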