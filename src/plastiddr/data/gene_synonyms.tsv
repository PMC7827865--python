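alias	canonical
psba	psbA
rbcl	rbcL
rpob	rpoB
rrn16s	rrn16
rrn23s	rrn23
rrn4.5s	rrn4.5
rrn5s	rrn5
16s rrna	rrn16
23s rrna	rrn23
5s rrna	rrn5
4.5s rrna	rrn4.5
infa	infA
matk	matK
cema	cemA
accd	accD
clpp1	clpP
clpp	clpP
ycf3a	ycf3
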