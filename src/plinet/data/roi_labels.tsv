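label	hemisphere	lobe
L-SFG	L	frontal
L-rMFG	L	frontal
L-cMFG	L	frontal
L-IFGop	L	frontal
L-IFGtr	L	frontal
L-IFGor	L	frontal
L-OFG	L	frontal
L-PreCG	L	frontal
L-rACC	L	cingular
L-cACC	L	cingular
L-PCC	L	cingular
L-ISTC	L	cingular
L-HES	L	temporal
L-STG	L	temporal
L-MTG	L	temporal
L-ITG	L	temporal
L-FFG	L	temporal
L-PoCG	L	parietal
L-SPG	L	parietal
L-IPG	L	parietal
L-SMG	L	parietal
L-PCUN	L	parietal
R-SFG	R	frontal
R-rMFG	R	frontal
R-cMFG	R	frontal
R-IFGop	R	frontal
R-IFGtr	R	frontal
R-IFGor	R	frontal
R-OFG	R	frontal
R-PreCG	R	frontal
R-rACC	R	cingular
R-cACC	R	cingular
R-PCC	R	cingular
R-ISTC	R	cingular
R-HES	R	temporal
R-STG	R	temporal
R-MTG	R	temporal
R-ITG	R	temporal
R-FFG	R	temporal
R-PoCG	R	parietal
R-SPG	R	parietal
R-IPG	R	parietal
R-SMG	R	parietal
R-PCUN	R	parietal
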