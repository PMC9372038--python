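name	pattern	category
ABRE	ACGTG	phytohormone_responsiveness
CGTCA-motif	CGTCA	phytohormone_responsiveness
TGACG-motif	TGACG	phytohormone_responsiveness
TCA-element	CCATCTTTTT	phytohormone_responsiveness
GARE-motif	TCTGTTG	phytohormone_responsiveness
TGA-element	AACGAC	phytohormone_responsiveness
P-box	CCTTTTG	phytohormone_responsiveness
MBS	CAACTG	stress_responsiveness
ARE	AAACCA	stress_responsiveness
LTR	CCGAAA	stress_responsiveness
STRE	AGGGG	stress_responsiveness
TC-rich repeats	ATTCTCTAAC	stress_responsiveness
As-1	TGACGTCA	stress_responsiveness
WUN-motif	AAATTTCCT	stress_responsiveness
WRE3	CCACCT	stress_responsiveness
DRE	RCCGAC	stress_responsiveness
CAT-box	GCCACT	growth_development
O2-site	GATGAYRTGR	growth_development
circadian	CAANNNNATC	growth_development
GCN4-motif	TGAGTCA	growth_development
RY-element	CATGCATG	growth_development
CAAT-box	CCAAT	core_promoter
TATA-box	TATAAA	core_promoter
Unnamed-1	CGTGG	uncharacterized
Unnamed-2	GTCTTTTC	uncharacterized
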