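code	description
ACE-I	ACE inhibitor
ACE2-I	ACE2 inhibitor
A-C-I	Alanine carboxypeptidase inhibitor
A-A-I	Alpha-amylase inhibitor
A-G-I	Alpha-glucosidase inhibitor
A-I	Anti-inflammatory
AAM	Antiamnestic
A-B	Antibacterial
AO	Antioxidative
AT	Antithrombotic
CaMPDE-I	CaMPDE inhibitor
D-A-D-DP-I	D-Ala-D-Ala dipeptidase inhibitor
DPP-III-I	Dipeptidyl peptidase III inhibitor
DPP-IV-I	Dipeptidyl peptidase IV inhibitor
H	Hypotensive
I	Inhibitor
I-C-A-AP	Inhibitor of cytosol alanyl aminopeptidase
I-TPP-II	Inhibitor of tripeptidyl peptidase II
L-I	Lactocepin inhibitor
NP	Neuropeptide
N-I	Neprilysin inhibitor
P-L-I	Pancreatic lipase inhibitor
PL-A2-I	Phospholipase A2 inhibitor
RL	Regulating
R-I	Renin inhibitor
S	Stimulating
X-P-I	Xaa-Pro inhibitor
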