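me_type	count
L1_HAC_cNAC	338
L23_PC_cADpyr	5877
L23_MC_cACint	824
L23_LBC_bNAC	823
L4_SS_cADpyr	4000
L4_MC_cACint	328
L4_LBC_cNAC	328
L5_TTPC2_cADpyr	5050
L5_MC_cACint	532
L5_LBC_bAC	532
L6_TPC_L4_cADpyr	11154
L6_MC_cACint	780
L6_LBC_cSTUT	780
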