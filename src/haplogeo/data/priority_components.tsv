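label	haplotypes	Ha	Hd	He	Hr	Hc	pi_ratio	H
ES	M	0	3	5	0	0	0	8
GD	A	0	3	0	0	3	0	6
DA	D	7	0	0	5	0	0	12
XN	D	7	0	0	5	0	0	12
JN	A	0	3	0	0	3	0	6
LQ	A	0	3	0	0	3	0	6
CY	A+B	0	3+3	5	5	3	0	19
LN	A	0	3	0	0	3	0	6
LP	D+E+C	7+7	3	5	5+5	3	0.7	35.7
NP	A	0	3	0	0	3	0	6
GP	A	0	3	0	0	3	0	6
PB	F	7	0	5	0	0	0	12
LS	D+E	7+7	0	0	5+5	0	1.8	25.8
JX	L	0	3	5	0	0	0	8
CH	H	0	3	0	5	0	0	8
HZ	H+I+J	0	3+3+3	5+5	0	3	1.7	23.7
SX	A	0	3	0	0	3	0	6
QY	G	0	3	5	0	0	0	8
LZ	A	0	3	0	0	3	0	6
LTJ	A	0	3	0	0	3	0	6
XHS	A	0	3	0	0	3	0	6
MS	A	0	3	0	0	3	0	6
TB	K	0	3	5	0	0	0	8
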