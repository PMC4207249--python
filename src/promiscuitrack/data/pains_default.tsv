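pattern_id	smarts	description
rhodanine	O=C1CSC(=S)N1	rhodanine / 2-thioxothiazolidin-4-one core
catechol	Oc1ccccc1O	ortho-dihydroxybenzene (catechol)
para_quinone	O=C1C=CC(=O)C=C1	para-quinone
ortho_quinone	O=C1C(=O)C=CC=C1	ortho-quinone
phenol_hydrazone	Oc1ccccc1C=NN	2-hydroxyphenyl hydrazone
aryl_azo	cN=Nc	aromatic azo bridge
isothiazolone	O=C1C=CSN1	isothiazol-3(2H)-one
alkylidene_barbiturate	O=C1NC(=O)NC(=O)C1=[#6]	alkylidene barbiturate
ene_one_ene	C=CC(=O)C=C	cross-conjugated dienone
beta_nitrostyrene	[O-][N+](=O)C=Cc1ccccc1	beta-nitrostyrene
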