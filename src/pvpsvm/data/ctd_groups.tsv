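# Three-group residue partitions for the seven CTD physicochemical properties
# (Dubchak-style protein-fold-class descriptor tables). Each row's three groups
# partition the 20-letter alphabet exactly.
property	group1	group2	group3
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
normalized_vdw_volume	GASCTPD	NVEQIL	MHKFRYW
polarity	LIFWCMVY	PATGS	HQRKNED
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
secondary_structure	EALMQKRH	VIYCWFT	GNPSD
solvent_accessibility	ALFCGIVW	RKQEND	MPSTHY
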