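gene	name	ensembl_id	rna_tissue_enrichment
APOB	Apolipoprotein B	ENSG00000084674	intestine: 224.8;liver: 442.2
APOF	Apolipoprotein F	ENSG00000175336	liver: 114.0
ASGR2	Asialoglycoprotein receptor 2	ENSG00000161944	liver: 154.1
C9	Complement C9	ENSG00000113600	liver: 419.5
CPB2	Carboxypeptidase B2	ENSG00000080618	liver: 246.8
CPN2	Carboxypeptidase N subunit 2	ENSG00000178772	liver: 225.5
CRP	C-reactive protein	ENSG00000132693	liver: 1139.7
CYP2E1	Cytochrome P450 family 2 subfamily E member 1	ENSG00000130649	liver: 802.4
DPYS	Dihydropyrimidinase	ENSG00000147647	kidney: 42.2;liver: 103.6
FGA	Fibrinogen alpha chain	ENSG00000171560	liver: 2009.3
FGB	Fibrinogen beta chain	ENSG00000171564	liver: 1908.6
FGG	Fibrinogen gamma chain	ENSG00000171557	liver: 2225.7
FGL1	Fibrinogen like 1	ENSG00000104760	liver: 450.7
GC	GC, vitamin D binding protein	ENSG00000145321	liver: 552.1
HPR	Haptoglobin-related protein	ENSG00000261701	liver: 151.4
ITIH3	Inter-alpha-trypsin inhibitor heavy chain 3	ENSG00000162267	liver: 326.9
ITIH4	Inter-alpha-trypsin inhibitor heavy chain family member 4	ENSG00000055955	liver: 461.4
LBP	Lipopolysaccharide binding protein	ENSG00000129988	liver: 429.7
ORM1	Orosomucoid 1	ENSG00000229314	liver: 834.6
PRG4	Proteoglycan 4	ENSG00000116690	adipose tissue: 20.9;liver: 76.0
VTN	Vitronectin	ENSG00000109072	liver: 321.7
SLC13A5	Solute carrier family 13 member 5	ENSG00000141485	liver: 150.4;salivary gland: 153.9
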