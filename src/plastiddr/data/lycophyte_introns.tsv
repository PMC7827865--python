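gene	category	intron_index	H.lu	H.se	I.fl	S.ly	S.kra	S.rem	S.ind	S.va	S.lep	S.san	S.st	S.ta	S.doe	S.inv	S.mo	S.bis	S.pen	S.hai	S.un
atpF	protein	1	+	+	+	+	+	+	-	-	+	+	+	+	+	+	+	+	+	+	+
clpP	protein	1	+	+	+	-	-	-	-	-	-	+	-	-	+	+	+	+	+	+	+
clpP	protein	2	+	+	+	-	-	-	-	-	-	+	-	-	+	-	-	-	-	-	-
ndhA	protein	1	+	+	+	.	+	+	.	.	.	.	.	.	+	+	+	.	+	+	+
ndhB	protein	1	+	+	+	.	+	+	.	.	.	.	.	.	+	+	+	.	+	+	+
petB	protein	1	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+
petD	protein	1	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+
rpl16	protein	1	+	+	+	+	+	+	+	+	+	+	.	.	+	+	+	+	+	+	+
rpl2	protein	1	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+
rpoC1	protein	1	+	+	+	-	+	+	+	+	+	+	+	+	+	+	+	.	+	+	+
rps12	protein	1	+	+	+	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
rps16	protein	1	+	+	-	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
ycf3	protein	1	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+	+
ycf3	protein	2	+	+	+	-	-	-	-	-	-	+	+	+	+	+	+	+	+	+	+
ycf66	protein	1	-	+	+	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
trnL	tRNA	1	+	+	+	-	.	-	.	.	-	-	.	.	-	.	.	.	.	.	.
trnG	tRNA	1	-	-	+	.	-	.	.	.	-	-	.	.	-	.	.	.	.	.	.
trnI	tRNA	1	.	+	+	.	.	.	.	.	.	-	.	.	.	-	-	.	.	.	.
trnA	tRNA	1	+	+	+	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
trnK	tRNA	1	.	+	+	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
trnV	tRNA	1	+	+	+	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.	.
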