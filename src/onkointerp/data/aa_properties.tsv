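# Per-amino-acid physicochemical properties used for substitution profiling.
# mw              : average molecular weight of the free amino acid (Da)
# charge          : net side-chain charge at pH 7 (-1, 0, +1; His counted +1
#                   for bridge detection, see docs)
# polar           : 1 if the side chain is polar
# aromatic        : 1 if the side chain is aromatic (F, W, Y, H)
# helix_breaker   : 1 for the classical alpha-helix breakers (P, G)
# beta_propensity : Chou-Fasman P(beta) sheet propensity
# hydropathy      : Kyte-Doolittle hydropathy index (solubility proxy)
# pi              : isoelectric point of the free amino acid (ionization potential proxy)
aa	mw	charge	polar	aromatic	helix_breaker	beta_propensity	hydropathy	pi
A	89.09	0	0	0	0	0.83	1.8	6.00
R	174.20	1	1	0	0	0.93	-4.5	10.76
N	132.12	0	1	0	0	0.89	-3.5	5.41
D	133.10	-1	1	0	0	0.54	-3.5	2.77
C	121.16	0	1	0	0	1.19	2.5	5.07
E	147.13	-1	1	0	0	0.37	-3.5	3.22
Q	146.15	0	1	0	0	1.10	-3.5	5.65
G	75.07	0	0	0	1	0.75	-0.4	5.97
H	155.16	1	1	1	0	0.87	-3.2	7.59
I	131.17	0	0	0	0	1.60	4.5	6.02
L	131.17	0	0	0	0	1.30	3.8	5.98
K	146.19	1	1	0	0	0.74	-3.9	9.74
M	149.21	0	0	0	0	1.05	1.9	5.74
F	165.19	0	0	1	0	1.38	2.8	5.48
P	115.13	0	0	0	1	0.55	-1.6	6.30
S	105.09	0	1	0	0	0.75	-0.8	5.68
T	119.12	0	1	0	0	1.19	-0.7	5.60
W	204.23	0	0	1	0	1.37	-0.9	5.89
Y	181.19	0	1	1	0	1.47	-1.3	5.66
V	117.15	0	0	0	0	1.70	4.2	5.96
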