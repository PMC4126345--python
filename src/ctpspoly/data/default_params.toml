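# Default thermodynamic parameters, produced by
# ctpspoly.estimation.calibrate_defaults() (deterministic; anchored to the
# published wild-type assay values: CTP IC50 = 360 uM at 0.2 uM enzyme,
# [CtpS]_0.5 = 3.3 uM at zero CTP and 1.4 uM at 800 uM CTP, maximal
# specific activity 6.7 1/s, all at 600 uM UTP).
# Units: dissociation constants in uM, E_nuc in k_B*T, k_max in 1/s.

[params]
K_uf = 600.0
K_cf = 179.96349477332774
K_cp = 121.87122484602814
K_e = 0.8315316850894845
E_nuc = 9.0
k_max = 13.4
mechanism = "competitive"
polymerizing = true
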