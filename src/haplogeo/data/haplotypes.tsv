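site	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15
region	rps8-rps11	rps8-rps11	rps8-rps11	rps8-rps11	rps8-rps11	rps16-trnQ	rps16-trnQ	rps16-trnQ	trnT-trnL	trnT-trnL	trnT-trnL	trnT-trnL	trnT-trnL	trnT-trnL	trnT-trnL
kind	substitution	substitution	indel	substitution	substitution	ssr	substitution	substitution	substitution	substitution	indel	substitution	indel	ssr	ssr
motif	.	.	TTCAAC	.	.	A	.	.	.	.	A	.	ATACTA	AT	A
A	C	G	-	A	C	9	A	A	C	G	-	C	-	6	10
B	C	G	-	A	C	9	A	A	C	G	-	C	+	6	10
C	C	G	+	C	C	10	T	T	C	G	A	T	-	6	10
D	C	G	+	C	C	10	T	T	C	G	A	T	-	8	10
E	C	G	+	C	C	10	T	T	C	G	-	C	-	8	10
F	C	G	+	C	C	10	T	T	C	G	-	C	-	7	10
G	C	A	+	C	C	10	T	T	A	G	-	C	-	5T	9
H	T	G	+	C	C	10	T	T	C	G	A	T	-	11	10
I	T	G	+	C	A	10	T	T	C	G	A	T	-	9	10
J	T	G	+	C	C	10	T	T	C	G	A	T	-	10	10
K	C	G	-	A	C	10	A	A	C	G	-	C	-	7	10
L	C	G	+	C	C	10	T	T	C	G	-	C	-	5T	9
M	C	G	+	C	C	10	T	T	C	T	A	T	-	8	10
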