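variant	domain	effect	ddg_inps3d	ddg_foldx	ddg_popmusic2	ispred4	rsa_percent
R46Q	catalytic	No effect on NAD(P) affinity	-0.76	-0.26	-1.05	N	29
R46W	catalytic	No effect on NAD(P) affinity	-0.5	-1.04	-0.35	N	29
R51P	catalytic		-1.24	-1.13	-1.47	N	49
R52Q	catalytic	Reduced affinity for NAD(P)	-1.06	0.08	-0.77	N	23
W59C	catalytic		-1.59	-3.58	-2.52	N	2
W59S	catalytic		-2.67	-3.92	-3.3	N	2
P66L	catalytic	NAD(P) binding site	-0.46	-4.09	-0.01	N	20
R68G	catalytic	Reduced affinity for NAD(P); NAD(P) binding site	-0.92	-0.4	-0.59	N	96
R82W	catalytic	No effect on NAD(P) affinity	-0.66	0.2	-0.81	N	44
A113T	catalytic	No effect NADPH	-1.17	-1.44	-1.71	N	0
A116T	catalytic		-0.65	-2.29	-1.95	N	0
H127Y	catalytic	FAD binding site	-0.18	1.37	-0.33	N	5
T129N	catalytic	Reduced affinity for NAD(P); FAD binding site	-1.17	-1.37	-0.81	N	7
C130R	catalytic	No effect on NAD(P) affinity	-1.99	-16.08	-1.34	N	1
T139M	catalytic		-0.34	0.83	0.29	N	18
Q147P	catalytic		-0.46	-2.95	-0.91	N	73
G149V	catalytic		-1.02	-13	-3.26	N	2
I153M	catalytic	No effect on NAD(P) affinity	-1.56	0.18	-1.71	N	1
R157Q	catalytic	No effect on NAD(P) affinity; FAD binding site	-1.31	-0.72	-0.57	N	25
A175T	catalytic	Reduced affinity for NAD(P); FAD binding site	-1.13	-0.73	-0.54	N	8
H181D	catalytic		-1.79	-2.23	-1.5	N	10
R183Q	catalytic	No effect on NAD(P) affinity	-1.48	-3.34	-0.82	N	16
C193Y	catalytic		-1.19	-10.91	-0.03	N	17
A195V	catalytic	Reduced affinity for NAD(P); FAD binding site	-0.43	0.39	0	N	11
G196D	catalytic	Reduced affinity for NAD(P)	-1.08	-3.26	-1.18	N	2
P202T	catalytic	FAD binding site	-0.73	-1.57	-0.16	N	68
V218L	catalytic	Decreased affinity for FAD	-1	-0.42	-0.42	N	12
A222V	catalytic	Decreased affinity for FAD	-0.71	-1.08	-0.09	N	11
I225L	catalytic	No effect on NAD(P) affinity	-1.32	-0.57	-1.17	N	0
T227M	catalytic		-1.58	-2.9	-0.14	N	1
P251L	catalytic		-0.56	0.62	-0.68	N	38
V253F	catalytic	Reduced affinity for NAD(P)	-0.82	-1.26	-1	N	0
P254S	catalytic	No effect on NAD(P) affinity	-1.22	-3.7	-0.86	N	0
G255V	catalytic		-0.55	-2.81	0.33	N	1
I256N	catalytic		-3.24	-3.27	-2.47	N	1
F257V	catalytic		-1.34	-1.61	-1.83	N	11
L323P	catalytic	Substrate binding site; NAD(P) binding site	-2.19	-4.95	-1.94	N	32
N324S	catalytic		-0.77	-3.52	-1.92	N	8
R325C	catalytic	Substrate binding site	-0.78	0.41	-0.34	N	43
L333P	catalytic		-3.39	-6.05	-3.62	N	0
R335C	catalytic		-0.67	-1.14	-0.86	N	60
M338T	regulatory		-1.58	-3.74	-1.21	N	18
W339G	regulatory		-2.78	-4.46	-2.55	N	20
R345C	regulatory		-0.67	-1.31	-0.23	N	43
P348S	regulatory	Reduced affinity for NAD(P); SAH binding site	-1.19	-3.53	-1.16	N	26
H354Y	regulatory	Reduced affinity for NAD(P)	-0.24	-0.2	-0.67	N	18
R357C	regulatory		-1.32	-2.3	-1.54	N	5
R357H	regulatory		-1.28	-1.09	-0.29	N	5
R363H	regulatory	Reduced affinity for NAD(P)	-1.39	-1.34	-0.83	N	6
K372E	regulatory	Reduced affinity for NAD(P)	-0.46	0.99	-0.31	N	52
R377C	regulatory	Reduced affinity for NAD(P)	-1.17	-3.99	-1.4	N	0
R377H	regulatory	Reduced affinity for NAD(P)	-1.2	-4.59	-0.68	N	0
W381R	regulatory		-1.83	-2.29	-1.95	N	14
G387D	regulatory	Reduced affinity for NAD(P)	-0.82	-3.35	-1.31	I	33
G390D	regulatory		-0.88	-2.23	0.13	N	64
W421S	regulatory	Reduced affinity for NAD(P)	-3.07	-6.97	-4	N	1
E429A	regulatory		-0.13	-0.79	0.2	N	50
F435S	regulatory		-3.45	-5.56	-2.94	N	1
S440L	regulatory		0.03	2.15	-0.55	N	25
Y506D	regulatory	Reduced affinity for NAD(P)	-1.77	-5.1	-3.16	I	61
Y512C	regulatory		-1.94	-4.31	-2.18	N	2
R535Q	regulatory		-0.79	-1.61	-0.77	N	25
R535W	regulatory		0.07	-1.39	-0.26	N	25
V536F	regulatory	Reduced affinity for NAD(P)	-1.38	-3.21	-0.6	N	1
P572L	regulatory	Reduced affinity for NAD(P)	-0.43	-7.32	-0.09	N	0
V574G	regulatory	Reduced affinity for NAD(P)	-3.32	-4.13	-3.47	N	1
V575G	regulatory	Reduced affinity for NAD(P)	-3.64	-4.06	-3.07	N	8
E586K	regulatory		-0.8	-5.23	-0.99	N	1
L598P	regulatory	Reduced affinity for NAD(P)	-2.49	-7.34	-2.68	N	22
S603C	regulatory		-1.03	-1.81	-0.7	N	15
L628P	regulatory	Reduced affinity for NAD(P)	-0.83	-4.47	-2.25	I	57
M338T	regulatory		-1.58	-3.74	-1.21	N	18
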