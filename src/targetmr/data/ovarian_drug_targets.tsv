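drug	target	mechanism
statins	HMGCR	HMG-CoA reductase inhibition
statins	ITGAL	integrin alpha-L binding (lipophilic statins)
lonafarnib	FNTA	farnesyltransferase alpha-subunit inhibition
lonafarnib	FNTB	farnesyltransferase beta-subunit inhibition
quinacrine	PLA2G4A	cytosolic phospholipase A2 inhibition
aspirin	PTGS1	cyclooxygenase-1 inhibition
aspirin	HSPA5	BiP/GRP78 modulation
aspirin	NEU1	neuraminidase-1 modulation
aspirin	CCND1	cyclin D1 downregulation
aspirin	CASP1	caspase-1 modulation
aspirin	CASP3	caspase-3 modulation
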