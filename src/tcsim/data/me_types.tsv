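me_type	excitatory
L1_DAC_cNAC	0
L1_HAC_cNAC	0
L1_SAC_bNAC	0
L1_NGC-DA_cNAC	0
L23_PC_cADpyr	1
L23_MC_cACint	0
L23_LBC_bNAC	0
L23_NBC_dNAC	0
L23_SBC_bNAC	0
L23_SBC_dNAC	0
L23_ChC_cACint	0
L23_DBC_cACint	0
L23_BTC_cACint	0
L23_BP_cACint	0
L4_PC_cADpyr	1
L4_SS_cADpyr	1
L4_SP_cADpyr	1
L4_MC_cACint	0
L4_LBC_cNAC	0
L4_DBC_bAC	0
L4_SBC_cACint	0
L4_BP_bNAC	0
L5_STPC_cADpyr	1
L5_TTPC1_cADpyr	1
L5_TTPC2_cADpyr	1
L5_UTPC_cADpyr	1
L5_MC_cACint	0
L5_LBC_bAC	0
L5_NBC_cACint	0
L5_BTC_bAC	0
L5_ChC_cACint	0
L6_TPC_L1_cADpyr	1
L6_TPC_L4_cADpyr	1
L6_IPC_cADpyr	1
L6_BPC_cADpyr	1
L6_UTPC_cADpyr	1
L6_MC_cACint	0
L6_LBC_cSTUT	0
L6_NBC_dNAC	0
L6_SBC_bNAC	0
L6_DBC_cACint	0
L6_BTC_cNAC	0
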