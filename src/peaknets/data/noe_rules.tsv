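# Default NOE peak-box generation rules for RNA secondary structure.
# Derived from A-form helix geometry: intra-residue sugar-to-base and
# pyrimidine H5-H6 contacts, the sequential aromatic-anomeric walk,
# adenine H2 sequential/cross-strand contacts, and imino-imino contacts
# between stacked base pairs.  Tetraloop rules continue the sequential
# walk through the four loop residues and the closing pair; they are an
# approximation to the stereotyped GNRA/UNCG patterns.
#
# Columns: context, pattern1, pattern2, offset
#   context: intra | helix_sequential | helix_crossstrand |
#            helix_pair_adjacent | tetraloop
#   pattern: atom name, AROM (H8 purine / H6 pyrimidine),
#            IMINO (H1 of G / H3 of U), or name@TYPE restriction
#   offset:  0 (same residue), +1 (next residue), partner+1
#            (cross-strand), +1pair (next stacked base pair)
intra	H1'	AROM	0
intra	H2'	AROM	0
intra	H3'	AROM	0
intra	H5	H6	0
helix_sequential	H1'	AROM	+1
helix_sequential	H2'	AROM	+1
helix_sequential	AROM	AROM	+1
helix_sequential	AROM	H5	+1
helix_sequential	H2@A	H1'	+1
helix_crossstrand	H2@A	H1'	partner+1
helix_pair_adjacent	IMINO	IMINO	+1pair
tetraloop	H1'	AROM	+1
tetraloop	H2'	AROM	+1
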