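source	category	count
CS	tcmsp_all	119
CX	tcmsp_all	189
DS	tcmsp_all	202
DG	tcmsp_all	125
HH	tcmsp_all	189
CS	tcmsp_selected	31
CX	tcmsp_selected	18
DS	tcmsp_selected	114
DG	tcmsp_selected	8
HH	tcmsp_selected	50
total	tcmsp_all_distinct	728
total	tcmsp_selected_distinct	205
literature	literature_selected	36
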