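"""Encode a single protein sequence into the 583-dimensional hybrid vector.

The vector concatenates five descriptor blocks: amino-acid composition
(AAC, 20), atomic composition (ATC, 5), composition/transition/distribution
descriptors over seven physicochemical properties (CTD, 147), dipeptide
composition (DPC, 400) and physicochemical class fractions plus a rescaled
mean residue mass (PCP, 11).  Every component lies in [0, 1].
"""

from pvpsvm import BLOCKS, ProteinSequence, encode, feature_names

seq = ProteinSequence(id="demo", residues="MKVLAWGRQNSTEEDFHKKRRPLC")
vector = encode(seq)
names = feature_names()

print(f"sequence {seq.id!r}, length {len(seq)}")
print(f"feature vector length: {len(vector)}")
for block, sl in BLOCKS.items():
    v = vector[sl]
    print(f"  {block:>3}: {sl.stop - sl.start:3d} components, sum {v.sum():.4f}")

top = sorted(zip(names, vector), key=lambda t: -t[1])[:5]
print("largest components (fractions of the sequence they describe):")
for name, value in top:
    print(f"  {name:30s} {value:.4f}")
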