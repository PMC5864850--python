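# Residue membership for the ten physicochemical class attributes
# (Taylor-style classification; "large" is the complement of "small").
class	members
polar	RNDQEHKSTWY
hydrophobic	ACFGHIKLMTVWY
charged	DEHKR
aliphatic	ILV
aromatic	FHWY
positively_charged	HKR
negatively_charged	DE
small	ACDGNPSTV
tiny	ACGS
large	EFHIKLMQRWY
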