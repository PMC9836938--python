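# Monomer registry: id	name	formula(free monomer)	backbone_link	side_chain_class
# Canonical amino acids (one-letter ids), free-acid formulas.
G	Gly	C2H5NO2	amide	canonical
A	Ala	C3H7NO2	amide	canonical
S	Ser	C3H7NO3	amide	canonical
P	Pro	C5H9NO2	amide	canonical
V	Val	C5H11NO2	amide	canonical
T	Thr	C4H9NO3	amide	canonical
C	Cys	C3H7NO2S	amide	canonical
L	Leu	C6H13NO2	amide	canonical
I	Ile	C6H13NO2	amide	canonical
N	Asn	C4H8N2O3	amide	canonical
D	Asp	C4H7NO4	amide	canonical
Q	Gln	C5H10N2O3	amide	canonical
K	Lys	C6H14N2O2	amide	canonical
E	Glu	C5H9NO4	amide	canonical
M	Met	C5H11NO2S	amide	canonical
H	His	C6H9N3O2	amide	canonical
F	Phe	C9H11NO2	amide	canonical
R	Arg	C6H14N4O2	amide	canonical
Y	Tyr	C9H11NO3	amide	canonical
W	Trp	C11H12N2O2	amide	canonical
# Non-canonical amino acids 1-5. Carbamates of lysine (1,2,4) and
# para-substituted phenylalanines (3,5).
1	AllocK	C10H18N2O4	amide	aliphatic
2	AlkynK	C10H16N2O4	amide	aliphatic
3	pIF	C9H10INO2	amide	aromatic
4	CbzK	C14H20N2O4	amide	aliphatic
5	pAzF	C9H10N4O2	amide	aromatic
# Alpha hydroxy acids 6-16 (alpha-OH instead of alpha-NH2 -> ester backbone
# link). 6-13 aliphatic side chains on the 6-amino-2-hydroxyhexanoic acid
# scaffold (13 is its N-acetyl); 14-16 aromatic side chains on the beta carbon.
6	BocK-OH	C11H21NO5	ester	aliphatic
7	AllocK-OH	C10H17NO5	ester	aliphatic
8	AlkynK-OH	C10H15NO5	ester	aliphatic
9	ButK-OH	C11H17NO5	ester	aliphatic
10	PenK-OH	C12H19NO5	ester	aliphatic
11	NorK-OH	C15H23NO5	ester	aliphatic
12	CbzK-OH	C14H19NO5	ester	aliphatic
13	AcK-OH	C8H15NO4	ester	aliphatic
14	F-OH	C9H10O3	ester	aromatic
15	pIF-OH	C9H9IO3	ester	aromatic
16	NapA-OH	C13H12O3	ester	aromatic
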