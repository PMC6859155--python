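# Bundled residue-average chemical shifts for the 20 standard amino acids
# (ppm), approximate consensus values in the style of the BMRB averaged
# statistics.  Columns: residue, atom (glob patterns allowed), ppm.
# Exact atom names take precedence over pattern rows.
ALA	N	123.4
ALA	H	8.20
ALA	CA	53.1
ALA	HA	4.26
ALA	CB	19.0
ALA	HB*	1.35
ARG	N	120.8
ARG	H	8.23
ARG	CA	56.8
ARG	HA	4.30
ARG	CB	30.7
ARG	HB*	1.79
ARG	CG	27.2
ARG	HG*	1.57
ARG	CD	43.2
ARG	HD*	3.12
ARG	NE	84.6
ARG	HE	7.30
ASN	N	118.9
ASN	H	8.33
ASN	CA	53.5
ASN	HA	4.67
ASN	CB	38.7
ASN	HB2	2.81
ASN	HB3	2.75
ASN	ND2	112.8
ASN	HD21	7.35
ASN	HD22	7.14
ASP	N	120.6
ASP	H	8.31
ASP	CA	54.7
ASP	HA	4.59
ASP	CB	40.9
ASP	HB2	2.72
ASP	HB3	2.66
CYS	N	118.8
CYS	H	8.38
CYS	CA	58.2
CYS	HA	4.66
CYS	CB	32.8
CYS	HB2	2.95
CYS	HB3	2.90
GLN	N	119.9
GLN	H	8.22
GLN	CA	56.6
GLN	HA	4.27
GLN	CB	29.2
GLN	HB*	2.04
GLN	CG	33.8
GLN	HG*	2.32
GLN	NE2	111.8
GLN	HE21	7.23
GLN	HE22	7.14
GLU	N	120.7
GLU	H	8.33
GLU	CA	57.3
GLU	HA	4.25
GLU	CB	30.0
GLU	HB*	2.01
GLU	CG	36.1
GLU	HG*	2.27
GLY	N	109.7
GLY	H	8.33
GLY	CA	45.4
GLY	HA2	3.96
GLY	HA3	3.90
HIS	N	119.6
HIS	H	8.25
HIS	CA	56.5
HIS	HA	4.61
HIS	CB	30.3
HIS	HB2	3.11
HIS	HB3	3.05
HIS	CD2	120.0
HIS	HD2	7.05
HIS	CE1	137.0
HIS	HE1	8.10
ILE	N	121.5
ILE	H	8.26
ILE	CA	61.6
ILE	HA	4.17
ILE	CB	38.6
ILE	HB	1.79
ILE	CG1	27.7
ILE	HG12	1.27
ILE	HG13	1.21
ILE	CG2	17.5
ILE	HG2*	0.79
ILE	CD1	13.4
ILE	HD1*	0.69
LEU	N	121.9
LEU	H	8.22
LEU	CA	55.6
LEU	HA	4.32
LEU	CB	42.3
LEU	HB2	1.65
LEU	HB3	1.62
LEU	CG	26.8
LEU	HG	1.51
LEU	CD1	24.7
LEU	HD1*	0.76
LEU	CD2	24.1
LEU	HD2*	0.73
LYS	N	121.4
LYS	H	8.25
LYS	CA	56.9
LYS	HA	4.26
LYS	CB	32.8
LYS	HB*	1.77
LYS	CG	24.9
LYS	HG*	1.38
LYS	CD	28.9
LYS	HD*	1.61
LYS	CE	41.9
LYS	HE*	2.93
LYS	NZ	33.0
LYS	HZ*	7.52
MET	N	120.1
MET	H	8.26
MET	CA	56.1
MET	HA	4.41
MET	CB	33.0
MET	HB*	2.01
MET	CG	32.0
MET	HG*	2.41
MET	CE	17.0
MET	HE*	1.86
PHE	N	120.7
PHE	H	8.36
PHE	CA	58.1
PHE	HA	4.62
PHE	CB	39.9
PHE	HB2	2.99
PHE	HB3	2.94
PHE	CD1	131.6
PHE	CD2	131.6
PHE	HD1	7.06
PHE	HD2	7.06
PHE	CE1	130.7
PHE	CE2	130.7
PHE	HE1	7.08
PHE	HE2	7.08
PHE	CZ	129.2
PHE	HZ	7.00
PRO	CA	63.3
PRO	HA	4.40
PRO	CB	31.8
PRO	HB2	2.07
PRO	HB3	2.01
PRO	CG	27.2
PRO	HG*	1.91
PRO	CD	50.3
PRO	HD2	3.64
PRO	HD3	3.60
SER	N	116.3
SER	H	8.29
SER	CA	58.7
SER	HA	4.51
SER	CB	63.8
SER	HB2	3.87
SER	HB3	3.85
THR	N	115.4
THR	H	8.24
THR	CA	62.2
THR	HA	4.46
THR	CB	69.7
THR	HB	4.16
THR	CG2	21.5
THR	HG2*	1.14
TRP	N	121.6
TRP	H	8.28
TRP	CA	57.7
TRP	HA	4.70
TRP	CB	30.3
TRP	HB2	3.19
TRP	HB3	3.12
TRP	CD1	126.5
TRP	HD1	7.14
TRP	NE1	129.3
TRP	HE1	10.10
TRP	CE3	120.5
TRP	HE3	7.30
TRP	CZ2	114.4
TRP	HZ2	7.40
TRP	CZ3	121.5
TRP	HZ3	7.00
TRP	CH2	123.8
TRP	HH2	7.10
TYR	N	120.9
TYR	H	8.33
TYR	CA	58.0
TYR	HA	4.60
TYR	CB	39.2
TYR	HB2	2.91
TYR	HB3	2.85
TYR	CD1	132.9
TYR	CD2	132.9
TYR	HD1	7.00
TYR	HD2	7.00
TYR	CE1	118.0
TYR	CE2	118.0
TYR	HE1	6.77
TYR	HE2	6.77
VAL	N	121.1
VAL	H	8.25
VAL	CA	62.5
VAL	HA	4.13
VAL	CB	32.7
VAL	HB	2.05
VAL	CG1	21.3
VAL	HG1*	0.84
VAL	CG2	20.6
VAL	HG2*	0.83
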