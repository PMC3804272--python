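aa	aa3	class	rank
R	Arg	B	20
S	Ser	B	19
V	Val	B	18
D	Asp	B	17
G	Gly	B	16
N	Asn	N	7
K	Lys	N	6
P	Pro	N	5
I	Ile	N	4
T	Thr	N	3
Q	Gln	N	2
Y	Tyr	N	1
L	Leu	I
H	His	I
F	Phe	I
M	Met	I
E	Glu	I
A	Ala	I
C	Cys	I
W	Trp	I
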