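region	population
Group I	CY
Group I	JN
Group I	LQ
Group I	SX
Group I	LTJ
Group I	GD
Group I	NP
Group I	GP
Group I	TB
Group I	LN
Group I	XHS
Group I	LZ
Group I	MS
Group II	QY
Group III	LP
Group III	DA
Group III	XN
Group III	ES
Group IV	CH
Group IV	HZ
Group V	LS
Group V	PB
Group V	JX
SW China	LP
SW China	PB
Central China	CY
Central China	DA
Central China	GD
Central China	LN
Central China	XN
Central China	ES
Eastern China	JN
Eastern China	LQ
Eastern China	GP
Eastern China	NP
Eastern China	TB
Lingnan	SX
Lingnan	LTJ
Lingnan	LS
Lingnan	QY
Lingnan	CH
Lingnan	HZ
Lingnan	JX
Lingnan	XHS
Lingnan	LZ
Lingnan	MS
Southern Nanling	SX
Southern Nanling	LTJ
Southern Nanling	LS
Southern Nanling	PB
Southern Nanling	QY
Southern Nanling	CH
Southern Nanling	HZ
Southern Nanling	JX
Southern Nanling	XHS
Southern Nanling	LZ
Northern Nanling	CY
Northern Nanling	JN
Northern Nanling	LQ
Northern Nanling	LP
Northern Nanling	GD
Northern Nanling	DA
Northern Nanling	NP
Northern Nanling	GP
Northern Nanling	TB
Northern Nanling	LN
Northern Nanling	XN
Northern Nanling	ES
Northern Nanling	MS
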