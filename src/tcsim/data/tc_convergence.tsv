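# Synthetic fixture: per-me-type thalamocortical convergence (presynaptic thalamic
# cells per cortical target cell, full-scale column).  Values are illustrative
# stand-ins for figure-only data and are NOT experimental measurements.
me_type	VPL	VPM	POm
L1_HAC_cNAC	5	5	20
L23_PC_cADpyr	20	20	15
L23_MC_cACint	20	20	15
L23_LBC_bNAC	20	20	15
L4_SS_cADpyr	120	120	10
L4_MC_cACint	120	120	10
L4_LBC_cNAC	120	120	10
L5_TTPC2_cADpyr	60	60	40
L5_MC_cACint	60	60	40
L5_LBC_bAC	60	60	40
L6_TPC_L4_cADpyr	40	40	15
L6_MC_cACint	40	40	15
L6_LBC_cSTUT	40	40	15
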