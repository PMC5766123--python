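label	lat	lon	n	A	B	C	D	E	F	G	H	I	J	K	L	M
ES	30.048333	109.133611	12	0	0	0	0	0	0	0	0	0	0	0	0	12
GD	25.939444	113.680000	12	12	0	0	0	0	0	0	0	0	0	0	0	0
DA	26.397500	111.299722	12	0	0	0	12	0	0	0	0	0	0	0	0	0
XN	26.608611	111.090556	12	0	0	0	12	0	0	0	0	0	0	0	0	0
JN	27.973333	119.635833	12	12	0	0	0	0	0	0	0	0	0	0	0	0
LQ	28.074722	119.141389	12	12	0	0	0	0	0	0	0	0	0	0	0	0
CY	25.681944	114.308333	11	7	4	0	0	0	0	0	0	0	0	0	0	0
LN	24.911111	114.789722	12	12	0	0	0	0	0	0	0	0	0	0	0	0
LP	26.230278	109.136667	12	0	0	1	10	1	0	0	0	0	0	0	0	0
NP	26.641667	118.177500	12	12	0	0	0	0	0	0	0	0	0	0	0	0
GP	27.797778	117.709444	12	12	0	0	0	0	0	0	0	0	0	0	0	0
PB	22.983611	103.687500	8	0	0	0	0	0	8	0	0	0	0	0	0	0
LS	25.625278	109.919722	12	0	0	0	9	3	0	0	0	0	0	0	0	0
JX	24.159722	110.211667	12	0	0	0	0	0	0	0	0	0	0	0	12	0
CH	23.548333	113.586389	9	0	0	0	0	0	0	0	9	0	0	0	0	0
HZ	23.632500	113.868333	12	0	0	0	0	0	0	0	6	3	3	0	0	0
SX	24.705833	114.259722	12	12	0	0	0	0	0	0	0	0	0	0	0	0
QY	24.726111	112.286944	12	0	0	0	0	0	0	12	0	0	0	0	0	0
LZ	24.773333	112.688889	12	12	0	0	0	0	0	0	0	0	0	0	0	0
LTJ	24.924444	113.032778	10	10	0	0	0	0	0	0	0	0	0	0	0	0
XHS	24.978611	113.032778	7	7	0	0	0	0	0	0	0	0	0	0	0	0
MS	24.978611	112.850833	7	7	0	0	0	0	0	0	0	0	0	0	0	0
TB	25.126111	121.859444	12	0	0	0	0	0	0	0	0	0	0	12	0	0
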