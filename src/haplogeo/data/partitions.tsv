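k	population	group
2	CY	1
2	JN	1
2	LQ	1
2	SX	1
2	LTJ	1
2	GD	1
2	NP	1
2	GP	1
2	TB	1
2	LN	1
2	XHS	1
2	LZ	1
2	MS	1
2	LP	2
2	DA	2
2	LS	2
2	PB	2
2	QY	2
2	CH	2
2	HZ	2
2	JX	2
2	XN	2
2	ES	2
3	CY	1
3	JN	1
3	LQ	1
3	SX	1
3	LTJ	1
3	GD	1
3	NP	1
3	GP	1
3	TB	1
3	LN	1
3	XHS	1
3	LZ	1
3	MS	1
3	LP	2
3	DA	2
3	LS	2
3	PB	2
3	CH	2
3	HZ	2
3	JX	2
3	XN	2
3	ES	2
3	QY	3
4	CY	1
4	JN	1
4	LQ	1
4	SX	1
4	LTJ	1
4	GD	1
4	NP	1
4	GP	1
4	TB	1
4	LN	1
4	XHS	1
4	LZ	1
4	MS	1
4	LP	2
4	DA	2
4	LS	2
4	PB	2
4	JX	2
4	XN	2
4	ES	2
4	QY	3
4	CH	4
4	HZ	4
5	CY	1
5	JN	1
5	LQ	1
5	SX	1
5	LTJ	1
5	GD	1
5	NP	1
5	GP	1
5	TB	1
5	LN	1
5	XHS	1
5	LZ	1
5	MS	1
5	QY	2
5	LP	3
5	DA	3
5	XN	3
5	ES	3
5	CH	4
5	HZ	4
5	LS	5
5	PB	5
5	JX	5
6	CY	1
6	JN	1
6	LQ	1
6	SX	1
6	LTJ	1
6	GD	1
6	NP	1
6	GP	1
6	TB	1
6	LN	1
6	XHS	1
6	LZ	1
6	LP	2
6	DA	2
6	XN	2
6	ES	2
6	QY	3
6	LS	4
6	PB	4
6	JX	4
6	CH	5
6	HZ	5
6	MS	6
7	CY	1
7	JN	1
7	LQ	1
7	SX	1
7	LTJ	1
7	GD	1
7	NP	1
7	GP	1
7	TB	1
7	LN	1
7	XHS	1
7	LZ	1
7	CH	2
7	HZ	2
7	LP	3
7	DA	3
7	XN	3
7	LS	4
7	PB	4
7	JX	4
7	ES	5
7	QY	6
7	MS	7
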