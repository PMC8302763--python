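label	cytoband	rsid	chrom	pos	a1	a2	a1_freq	odds_ratio	ci_low	ci_high	p	n_genes_region	implicated_genes	signal_location
a	1p11.1	rs3514182	1	12449403	T	C	0.38	1.11	1.07	1.16	2.85e-8	2	PPP2R5A,PACC1	proximal,distal
b	2q13	rs6708784	2	111927379	G	A	0.50	1.11	1.07	1.15	3.91e-8	2	BCL2L11	distal
c	5p15.33	rs7734992	5	1280128	T	C	0.60	1.32	1.26	1.37	5.17e-40	1	TERT	intronic
d	6p21.32	rs9469079	6	32032421	T	C	0.13	1.18	1.11	1.25	3.93e-9	1	TNXB	intronic
e	6p21.32	rs141079110	6	33533625	A	G	0.75	1.23	1.18	1.29	9.39e-22	1	BAK1	distal
f	8q24.12	rs9987332	8	120933963	A	G	0.44	1.12	1.08	1.16	2.34e-9	1	DEPTOR	intronic
g	9p24.3	rs10976519	9	779507	G	T	0.42	1.16	1.12	1.20	1.04e-15	0	DMRT1	proximal
h	9q33.3	rs10818964	9	127190340	G	A	0.67	1.13	1.09	1.18	7.92e-10	0	.	.
i	9q34.3	rs28393706	9	140073294	T	C	0.75	1.18	1.13	1.23	1.20e-11	3	SSNA1,ANAPC2,TPRN	intronic,proximal,distal
j	10p14	rs7912968	10	7534248	C	G	0.38	1.11	1.07	1.16	1.50e-8	0	.	.
k	11p14.1	rs7927974	11	30351223	G	A	0.29	1.12	1.08	1.17	4.03e-8	2	ARL14EP,MPPED2	intronic,distal
l	12p13.33	rs2887532	12	1051495	C	T	0.82	1.17	1.11	1.23	6.23e-10	1	RAD52	intronic
m	12q13.13	rs12830125	12	51301431	C	G	0.34	1.14	1.09	1.19	2.18e-9	2	.	.
n	12q13.2	rs35969688	12	53793209	A	G	0.18	1.17	1.12	1.23	4.32e-11	2	SP1,AMRH2	intronic,proximal
o	17q25.3	rs55779573	17	76691564	C	T	0.53	1.13	1.09	1.17	1.08e-10	2	CYTH1,USP36	intronic,distal
p	18p11.32	rs2847334	18	692095	G	A	0.57	1.11	1.07	1.16	4.16e-8	1	ENOSF1	intronic
q	19q12	rs8104804	19	28356614	C	T	0.19	1.17	1.12	1.23	1.38e-10	1	LOC101927151	intronic
r	20q13.2	rs6068588	20	52197366	A	C	0.12	1.18	1.11	1.25	1.32e-8	2	ZNF217	intronic
s	Xp22.11	rs72620486	X	24384181	T	C	0.15	1.14	1.09	1.19	2.74e-9	2	SUPT20HL1,PDK3	utr5,proximal
t	Xq12	rs2335864	X	66489986	G	A	0.20	1.15	1.10	1.20	3.39e-11	0	AR	proximal
u	Xq22.1	rs2360670	X	100432681	A	T	0.54	1.14	1.10	1.17	2.08e-15	2	CENPI,DPR2	distal,proximal
v	Xq28	rs4898474	X	153535143	C	T	0.31	1.18	1.14	1.22	3.60e-19	2	TKTL1	intronic,proximal
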