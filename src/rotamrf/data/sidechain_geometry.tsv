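# res	atom	a1	a2	a3	bond_A	angle_deg	chi	delta_deg
ALA	CB	CA	N	C	1.5294	109.465	0	-119.999
ARG	CB	CA	N	C	1.5363	111.550	0	-123.561
ARG	CG	CB	CA	N	1.5371	114.536	1	0.000
ARG	CD	CG	CB	CA	1.5273	112.417	2	0.000
ARG	NE	CD	CG	CB	1.4435	111.016	3	0.000
ARG	CZ	NE	CD	CG	1.4058	123.005	4	0.000
ARG	NH1	CZ	NE	CD	1.3906	120.996	0	179.986
ARG	NH2	CZ	NE	CD	1.3912	119.815	0	-0.012
ASN	CB	CA	N	C	1.5309	109.454	0	-119.996
ASN	CG	CB	CA	N	1.5066	109.484	1	0.000
ASN	OD1	CG	CB	CA	1.2133	119.974	2	0.000
ASN	ND2	CG	CB	CA	1.3476	120.012	2	-179.926
ASP	CB	CA	N	C	1.5301	109.480	0	-120.011
ASP	CG	CB	CA	N	1.5075	109.463	1	0.000
ASP	OD1	CG	CB	CA	1.2080	119.959	2	0.000
ASP	OD2	CG	CB	CA	1.3415	119.999	2	-179.936
CYS	CB	CA	N	C	1.5285	109.496	0	-120.014
CYS	SG	CB	CA	N	1.8141	109.498	1	0.000
GLN	CB	CA	N	C	1.5288	109.459	0	-120.066
GLN	CG	CB	CA	N	1.5284	109.534	1	0.000
GLN	CD	CG	CB	CA	1.5066	109.543	2	0.000
GLN	OE1	CD	CG	CB	1.2122	119.937	3	0.000
GLN	NE2	CD	CG	CB	1.3471	120.093	3	-179.957
GLU	CB	CA	N	C	1.5302	109.482	0	-119.956
GLU	CG	CB	CA	N	1.5306	109.402	1	0.000
GLU	CD	CG	CB	CA	1.5076	109.430	2	0.000
GLU	OE1	CD	CG	CB	1.2084	120.003	3	0.000
GLU	OE2	CD	CG	CB	1.3425	119.998	3	-179.937
HIS	CB	CA	N	C	1.5337	111.125	0	-122.779
HIS	CG	CB	CA	N	1.5100	112.979	1	0.000
HIS	ND1	CG	CB	CA	1.3513	120.329	2	0.000
HIS	CD2	CG	CB	CA	1.3376	129.928	2	179.846
HIS	CE1	ND1	CG	CB	1.3369	107.862	0	179.905
HIS	NE2	CD2	CG	CB	1.3739	105.332	0	-179.864
ILE	CB	CA	N	C	1.5288	109.430	0	-120.073
ILE	CG1	CB	CA	N	1.5294	109.547	1	0.000
ILE	CG2	CB	CA	N	1.5303	109.458	1	-119.972
ILE	CD1	CG1	CB	CA	1.5288	109.547	2	0.000
LEU	CB	CA	N	C	1.5286	109.416	0	-119.973
LEU	CG	CB	CA	N	1.5303	109.495	1	0.000
LEU	CD1	CG	CB	CA	1.5300	109.500	2	0.000
LEU	CD2	CG	CB	CA	1.5285	109.501	2	120.092
LYS	CB	CA	N	C	1.5300	109.453	0	-119.967
LYS	CG	CB	CA	N	1.5307	109.418	1	0.000
LYS	CD	CG	CB	CA	1.5308	109.441	2	0.000
LYS	CE	CD	CG	CB	1.5291	109.465	3	0.000
LYS	NZ	CE	CD	CG	1.4694	109.500	4	0.000
MET	CB	CA	N	C	1.5294	109.427	0	-120.037
MET	CG	CB	CA	N	1.5284	109.545	1	0.000
MET	SD	CG	CB	CA	1.8137	109.506	2	0.000
MET	CE	SD	CG	CB	1.8135	100.034	3	0.000
PHE	CB	CA	N	C	1.5289	109.474	0	-120.094
PHE	CG	CB	CA	N	1.5052	109.517	1	0.000
PHE	CD1	CG	CB	CA	1.3817	120.058	2	0.000
PHE	CD2	CG	CB	CA	1.3832	120.005	2	179.757
PHE	CE1	CD1	CG	CB	1.3820	120.029	0	179.994
PHE	CE2	CD2	CG	CB	1.3819	119.977	0	179.839
PHE	CZ	CE1	CD1	CG	1.3806	120.047	0	-0.048
PRO	CB	CA	N	C	1.5434	104.722	0	-118.841
PRO	CG	CB	CA	N	1.5426	105.059	1	0.000
PRO	CD	CG	CB	CA	1.5437	105.063	2	0.000
SER	CB	CA	N	C	1.5287	109.471	0	-120.020
SER	OG	CB	CA	N	1.4283	109.512	1	0.000
THR	CB	CA	N	C	1.5290	109.411	0	-120.000
THR	OG1	CB	CA	N	1.4280	109.505	1	0.000
THR	CG2	CB	CA	N	1.5301	109.525	1	-120.031
TRP	CB	CA	N	C	1.5286	109.523	0	-120.026
TRP	CG	CB	CA	N	1.5067	109.442	1	0.000
TRP	CD1	CG	CB	CA	1.3426	126.496	2	0.000
TRP	CD2	CG	CB	CA	1.4639	126.512	2	179.622
TRP	NE1	CD1	CG	CB	1.3686	109.932	0	179.944
TRP	CE2	CD2	CG	CB	1.4068	106.076	0	179.958
TRP	CE3	CD2	CG	CB	1.3961	134.047	0	0.784
TRP	CZ2	CE2	CD2	CG	1.3906	119.346	0	-179.825
TRP	CZ3	CE3	CD2	CG	1.3659	119.795	0	179.639
TRP	CH2	CZ2	CE2	CD2	1.3773	119.806	0	0.221
TYR	CB	CA	N	C	1.5287	109.470	0	-120.041
TYR	CG	CB	CA	N	1.5062	109.497	1	0.000
TYR	CD1	CG	CB	CA	1.3823	119.947	2	0.000
TYR	CD2	CG	CB	CA	1.3830	119.943	2	179.692
TYR	CE1	CD1	CG	CB	1.3810	120.073	0	-179.976
TYR	CE2	CD2	CG	CB	1.3809	120.020	0	179.775
TYR	CZ	CE1	CD1	CG	1.3867	119.978	0	-0.102
TYR	OH	CZ	CE1	CD1	1.3582	120.130	0	-179.966
VAL	CB	CA	N	C	1.5287	109.445	0	-120.004
VAL	CG1	CB	CA	N	1.5299	109.509	1	0.000
VAL	CG2	CB	CA	N	1.5292	109.490	1	120.026
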