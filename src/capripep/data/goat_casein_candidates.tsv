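peptide	score	activities	alleles
QGL	0.533495	ACE-I;DPP-IV-I	CSN1S1:A,B,E,F
QM	0.607122	-	CSN1S1:A,B,E,F
STF	0.58977	ACE-I;H;DPP-IV-I;DPP-III-I;R-I;P-L-I	CSN1S1:F
CPL	0.916551	ACE-I;DPP-IV-I;X-P-I;L-I	CSN1S1:F
VIW	0.610494	ACE-I;DPP-IV-I	CSN1S1:F
SF	0.948796	ACE-I;DPP-IV-I;R-I	CSN1S1:F|CSN3:A,B,C,D,E
GY	0.741592	ACE-I;DPP-IV-I;DPP-III-I	CSN1S1:A,B,E
SM	0.628268	DPP-III-I	CSN1S1:A,B,E
QPM	0.810167	ACE-I;DPP-IV-I	CSN1S1:A,B,E
PQL	0.527882	ACE-I;DPP-IV-I	CSN1S1:A,B,E
QF	0.946135	DPP-IV-I;R-I	CSN1S1:A,B,E|CSN1S2:A,B,C,F|CSN3:A,B,C,D,E
PSGAW	0.870583	ACE-I;AO;I;DPP-IV-I;A-C-I	CSN1S1:A,B,E
PL	0.811148	ACE-I;DPP-IV-I;X-P-I;L-I	CSN1S1:A,B,E|CSN2:A,C
AAM	0.55858	ACE-I;A-B;H;DPP-IV-I;I-TPP-II;I-C-A-AP;D-A-D-DP-I	CSN1S1:E
ACL	0.746733	-	CSN2:A,C
PF	0.99343	DPP-IV-I;DPP-III-I;ACE2-I	CSN2:A,C
PVEPF	0.604782	ACE-I;AO;DPP-IV-I;A-G-I;DPP-III-I;ACE2-I;N-I	CSN2:A,C
QPPQPL	0.823819	ACE-I;DPP-IV-I;A-G-I;X-P-I;L-I	CSN2:A,C
DM	0.607466	ACE-I	CSN2:A,C
PIQAF	0.749093	ACE-I;DPP-IV-I;I-TPP-II	CSN2:A,C
GPF	0.989324	AAM;ACE-I;AT;RL;AO;H;DPP-IV-I;DPP-III-I;ACE2-I;N-I	CSN2:A,C
PIL	0.641797	ACE-I;S;NP;DPP-IV-I	CSN2:A,C
IF	0.949173	ACE-I	CSN1S2:A,B,C,F
PR	0.787626	ACE-I;DPP-III-I	CSN1S2:A,B,C,F
PY	0.736696	NP;A-I;DPP-IV-I;PL-A2-I	CSN1S2:A,B,C,F|CSN3:A,B,C,D,E
PW	0.992911	AO;DPP-IV-I	CSN1S2:A,B,C,F
AGAF	0.873661	ACE-I;AO;DPP-IV-I;CaMPDE-I;I-TPP-II;A-C-I	CSN1S2:A,B,C
AGPF	0.969222	AAM;ACE-I;AT;RL;AO;DPP-IV-I;DPP-III-I;ACE2-I;N-I	CSN1S2:F
AW	0.9669	ACE-I;AO;DPP-IV-I	CSN1S2:A,B,C,F
AM	0.74549	-	CSN1S2:A,B,C,F
AIPY	0.613395	ACE-I;NP;A-I;DPP-IV-I;PL-A2-I	CSN1S2:A,B,C,F
GL	0.808777	ACE-I;DPP-IV-I	CSN3:A,B,C,D,E
QW	0.928524	DPP-IV-I	CSN3:A,B,C,D,E
PH	0.541688	ACE-I;DPP-IV-I;AO	CSN3:A,B,C,D,E
AIPPK	0.575607	A-A-I;ACE-I;AT;AO;A-I;DPP-IV-I;A-G-I;ACE2-I	CSN3:A,B,C,D,E
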