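# Bundled RNA chemical-shift lookup table (ppm).
# Approximate consensus values for A-form helical ("paired") and
# loop/single-stranded ("unpaired") nucleotides, assembled from published
# RNA shift statistics.  These provide plausible starting positions for
# peak-box networks; they are not a trained predictor and the file is the
# versioned contract for swapping in a better one.
#
# Row kinds (tab-separated):
#   context  <5-char window>  <atom>  <ppm>
#       window = residues i-2..i+2, paired residues UPPERCASE, unpaired
#       lowercase, '-' for positions past the sequence ends
#   pair     <residue>  paired|unpaired  <atom>  <ppm>
#   residue  <residue>  <atom>  <ppm>
#   delta    prev|next  purine|pyrimidine  <atom>  <delta-ppm>
#       additive ring-current-style neighbour corrections, applied on top
#       of the pair level when the full window is known
#   element  <element>  <ppm>
#       last-resort fallback so every queried atom gets a value
#
# --- exact-context entries (UUCG tetraloop signature, approximate) ---
context	UCuuc	H1'	5.95
context	UCuuc	H6	8.05
context	Cuucg	H1'	5.92
context	Cuucg	H6	7.98
context	uucgG	H1'	5.78
context	uucgG	H5	5.95
context	uucgG	H6	7.85
context	ucgGA	H1'	5.62
context	ucgGA	H8	7.28
# --- adenosine ---
pair	A	paired	H1'	5.48
pair	A	paired	H2'	4.55
pair	A	paired	H3'	4.58
pair	A	paired	H4'	4.46
pair	A	paired	H5'	4.44
pair	A	paired	H5''	4.12
pair	A	paired	H2	7.32
pair	A	paired	H8	7.96
pair	A	paired	H61	6.82
pair	A	paired	H62	7.88
pair	A	paired	C1'	92.4
pair	A	paired	C2'	75.3
pair	A	paired	C3'	72.6
pair	A	paired	C4'	82.4
pair	A	paired	C5'	65.3
pair	A	paired	C2	152.8
pair	A	paired	C8	139.0
pair	A	paired	N6	81.5
pair	A	unpaired	H1'	5.82
pair	A	unpaired	H2'	4.48
pair	A	unpaired	H3'	4.52
pair	A	unpaired	H4'	4.38
pair	A	unpaired	H5'	4.32
pair	A	unpaired	H5''	4.06
pair	A	unpaired	H2	7.96
pair	A	unpaired	H8	8.22
pair	A	unpaired	H61	6.95
pair	A	unpaired	H62	7.60
pair	A	unpaired	C1'	90.6
pair	A	unpaired	C2'	75.6
pair	A	unpaired	C3'	73.4
pair	A	unpaired	C4'	83.0
pair	A	unpaired	C5'	65.9
pair	A	unpaired	C2	154.3
pair	A	unpaired	C8	140.6
pair	A	unpaired	N6	80.8
# --- guanosine ---
pair	G	paired	H1'	5.62
pair	G	paired	H2'	4.50
pair	G	paired	H3'	4.48
pair	G	paired	H4'	4.42
pair	G	paired	H5'	4.40
pair	G	paired	H5''	4.08
pair	G	paired	H8	7.38
pair	G	paired	H1	12.85
pair	G	paired	H21	8.15
pair	G	paired	H22	6.55
pair	G	paired	C1'	92.7
pair	G	paired	C2'	75.2
pair	G	paired	C3'	72.4
pair	G	paired	C4'	82.2
pair	G	paired	C5'	65.6
pair	G	paired	C8	135.8
pair	G	paired	N1	147.2
pair	G	paired	N2	74.0
pair	G	unpaired	H1'	5.74
pair	G	unpaired	H2'	4.44
pair	G	unpaired	H3'	4.46
pair	G	unpaired	H4'	4.34
pair	G	unpaired	H5'	4.28
pair	G	unpaired	H5''	4.02
pair	G	unpaired	H8	7.92
pair	G	unpaired	H1	10.80
pair	G	unpaired	H21	7.10
pair	G	unpaired	H22	6.40
pair	G	unpaired	C1'	91.0
pair	G	unpaired	C2'	75.5
pair	G	unpaired	C3'	73.0
pair	G	unpaired	C4'	83.1
pair	G	unpaired	C5'	66.0
pair	G	unpaired	C8	137.6
pair	G	unpaired	N1	145.2
pair	G	unpaired	N2	74.6
# --- cytidine ---
pair	C	paired	H1'	5.46
pair	C	paired	H2'	4.42
pair	C	paired	H3'	4.46
pair	C	paired	H4'	4.40
pair	C	paired	H5'	4.46
pair	C	paired	H5''	4.10
pair	C	paired	H5	5.28
pair	C	paired	H6	7.52
pair	C	paired	H41	8.32
pair	C	paired	H42	6.92
pair	C	paired	C1'	93.4
pair	C	paired	C2'	75.1
pair	C	paired	C3'	71.9
pair	C	paired	C4'	81.6
pair	C	paired	C5'	64.5
pair	C	paired	C5	97.0
pair	C	paired	C6	140.2
pair	C	paired	N4	97.5
pair	C	unpaired	H1'	5.66
pair	C	unpaired	H2'	4.30
pair	C	unpaired	H3'	4.40
pair	C	unpaired	H4'	4.28
pair	C	unpaired	H5'	4.30
pair	C	unpaired	H5''	4.04
pair	C	unpaired	H5	5.88
pair	C	unpaired	H6	7.76
pair	C	unpaired	H41	7.75
pair	C	unpaired	H42	7.10
pair	C	unpaired	C1'	92.0
pair	C	unpaired	C2'	75.4
pair	C	unpaired	C3'	72.8
pair	C	unpaired	C4'	82.6
pair	C	unpaired	C5'	65.2
pair	C	unpaired	C5	98.1
pair	C	unpaired	C6	141.8
pair	C	unpaired	N4	96.8
# --- uridine ---
pair	U	paired	H1'	5.52
pair	U	paired	H2'	4.44
pair	U	paired	H3'	4.52
pair	U	paired	H4'	4.43
pair	U	paired	H5'	4.48
pair	U	paired	H5''	4.11
pair	U	paired	H5	5.18
pair	U	paired	H6	7.78
pair	U	paired	H3	13.60
pair	U	paired	C1'	93.2
pair	U	paired	C2'	75.2
pair	U	paired	C3'	72.2
pair	U	paired	C4'	81.8
pair	U	paired	C5'	64.8
pair	U	paired	C5	102.6
pair	U	paired	C6	141.9
pair	U	paired	N3	159.6
pair	U	unpaired	H1'	5.70
pair	U	unpaired	H2'	4.34
pair	U	unpaired	H3'	4.42
pair	U	unpaired	H4'	4.30
pair	U	unpaired	H5'	4.31
pair	U	unpaired	H5''	4.05
pair	U	unpaired	H5	5.78
pair	U	unpaired	H6	7.86
pair	U	unpaired	H3	11.10
pair	U	unpaired	C1'	91.8
pair	U	unpaired	C2'	75.6
pair	U	unpaired	C3'	73.1
pair	U	unpaired	C4'	82.8
pair	U	unpaired	C5'	65.5
pair	U	unpaired	C5	103.4
pair	U	unpaired	C6	143.0
pair	U	unpaired	N3	157.8
# --- residue-type averages (final sequence-level back-off) ---
residue	A	H1'	5.65
residue	A	H2	7.64
residue	A	H8	8.09
residue	G	H1'	5.68
residue	G	H8	7.65
residue	G	H1	11.80
residue	C	H1'	5.56
residue	C	H5	5.58
residue	C	H6	7.64
residue	U	H1'	5.61
residue	U	H5	5.48
residue	U	H6	7.82
residue	U	H3	12.35
# --- neighbour ring-current corrections (1H only) ---
delta	prev	purine	H1'	-0.12
delta	prev	purine	H5	-0.16
delta	prev	purine	H6	-0.08
delta	prev	purine	H8	-0.06
delta	prev	purine	H2	-0.04
delta	prev	pyrimidine	H1'	0.05
delta	prev	pyrimidine	H5	0.06
delta	prev	pyrimidine	H6	0.04
delta	prev	pyrimidine	H8	0.05
delta	prev	pyrimidine	H2	0.02
delta	next	purine	H1'	-0.06
delta	next	purine	H5	-0.07
delta	next	purine	H6	-0.04
delta	next	purine	H8	-0.03
delta	next	purine	H2	-0.02
delta	next	pyrimidine	H1'	0.03
delta	next	pyrimidine	H5	0.03
delta	next	pyrimidine	H6	0.02
delta	next	pyrimidine	H8	0.02
delta	next	pyrimidine	H2	0.01
# --- element-level fallback ---
element	H	6.50
element	C	90.0
element	N	150.0
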