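attribute	class1_name	class1	class2_name	class2	class3_name	class3
hydrophobicity	polar	RKEDQN	neutral	GASTPHY	hydrophobic	CLVIMFW
vdw_volume	small	GASTPD	medium	CNVEQIL	large	MHKFRYW
polarity	low	LIFWCMVY	medium	PATGS	high	HQRKNED
polarizability	low	GASDT	medium	CPNVEQIL	high	KMHFRYW
charge	positive	KR	neutral	ANCQGHILMFPSTWYV	negative	DE
secondary_structure	helix	EALMQKRH	strand	VIYCWFT	coil	GNPSD
solvent_accessibility	buried	ALFCGIVW	exposed	RKQEND	intermediate	MSPTHY
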