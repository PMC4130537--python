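clone	FR1_R	FR1_S	CDR1_R	CDR1_S	FR2_R	FR2_S	CDR2_R	CDR2_S	FR3_R	FR3_S
BR55-2	0	0	0	0	0	0	4	1	2	1
B3	0	0	0	0	0	0	6	1	3	3
BR96	3	0	0	0	0	0	4	0	0	1
mu3S193	0	1	0	0	0	0	5	0	2	0
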