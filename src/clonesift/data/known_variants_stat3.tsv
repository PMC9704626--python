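protein_change	exon	known_id	cadd
S590R	20		26.1
K591X	20		33
E592*	20		44
K601T	20		24.8
T605X	20		31
F606X	20		33
S614R	20	COSV52888203	29.4
E616*	20		43
E616del	20	COSV52882850	22.9
G617G	20		12
G618R	20	COSV52882950	32
P639Q	21		26.4
Y640F	21	COSV52882807	23.8
Q644H	21		23.7
N646K	21	OMIM #615952	23.3
N647I	21	COSV52882818	23.7
Y657dup	21	COSV52891910	21.9
K658N	21	COSV52886038 OMIM #615952	26.4
K658M	21	COSM1166797	28.8
K658R	21	COSV52886492	25
I659L	21	COSV52891525	24.4
D661Y	21	COSV52882933	25.3
D661V	21	COSV52886283	24.4
L666V	21		25.3
V671L	21		24
E690*	21		38
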