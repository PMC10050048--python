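# PDDG/MNDO parameter values used as an alternative optimization start
# (only the MNDO-shared parameters; Gaussian core-repulsion corrections of
# PDDG are not part of this formalism)
H alpha 2.491813
H beta_s -7.493504
H U_ss -11.724114
H zeta_s 1.322431
H E_isol -12.015956
C alpha 2.555522
C beta_s -18.841334
C beta_p -7.922234
C U_ss -53.837582
C U_pp -39.936409
C zeta_s 1.809817
C zeta_p 1.825008
C E_isol -123.864410
N alpha 2.843678
N beta_s -20.375774
N beta_p -21.085373
N U_ss -71.871894
N U_pp -58.216617
N zeta_s 2.231424
N zeta_p 2.253460
N E_isol -206.466630
O alpha 3.238842
O beta_s -33.606336
O beta_p -27.984442
O U_ss -97.884970
O U_pp -77.342674
O zeta_s 2.569172
O zeta_p 2.697152
O E_isol -310.879750
F alpha 3.322382
F beta_s -67.827612
F beta_p -40.924818
F U_ss -134.220380
F U_pp -107.155960
F zeta_s 4.328519
F zeta_p 2.905042
F E_isol -488.703240
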