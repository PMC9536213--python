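population	count
RTNo	727
RTNm	727
RTNi	1453
VPL	1453
VPM	1453
POm	2906
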