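# Synthetic stand-in for the annotated-gene universe of a perturbation
# reference database. Covers 21 of the 22 packaged signature genes; SLC13A5
# is deliberately absent (not annotated in the reference), plus a background
# of common well-measured genes.
APOB
APOF
ASGR2
C9
CPB2
CPN2
CRP
CYP2E1
DPYS
FGA
FGB
FGG
FGL1
GC
HPR
ITIH3
ITIH4
LBP
ORM1
PRG4
VTN
ACTB
GAPDH
TP53
MYC
EGFR
STAT3
IL6
KRAS
BRAF
PIK3CA
APC
SMAD4
CTNNB1
CDH1
VIM
ALB
TF
HP
SERPINA1
APOA1
APOA2
TTR
AHSG
F2
PLG
CYP3A4
CYP1A2
HNF4A
CEACAM5
LGR5
AXIN2
MKI67
CCND1
CDKN1A
BAX
BCL2
ALDH1A1
ALDH1A3
ABCB1
ABCG2
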