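# T-scale amino-acid property vectors (5 principal components of
# topological descriptors computed over 67 natural and modified amino
# acids), transcribed for the 20 standard residues.  Columns: residue,
# T1..T5.  The encoder standardizes each column to mean 0, variance 1
# over these 20 rows before use.
A	-9.11	-1.63	0.63	1.04	2.26
R	0.23	3.89	-1.16	-0.39	-0.06
N	-4.62	0.66	1.16	-0.22	0.93
D	-4.65	0.75	1.39	-0.40	1.05
C	-7.35	-0.86	-0.33	0.80	0.98
Q	-3.00	1.72	0.28	-0.39	0.33
E	-3.03	1.82	0.51	-0.58	0.43
G	-10.61	-1.21	-0.12	0.75	3.25
H	-1.01	-1.31	0.01	-1.81	-0.21
I	-4.25	-0.28	-0.15	1.40	-0.21
L	-4.38	0.28	-0.49	1.45	0.02
K	-2.59	2.34	-1.69	0.41	-0.21
M	-4.08	0.98	-2.34	1.64	-0.79
F	0.49	-0.94	-0.63	-1.27	-0.44
P	-5.11	-3.54	-0.53	-0.36	-0.29
S	-7.44	-0.65	0.68	-0.17	1.58
T	-5.97	-0.62	1.11	0.31	0.95
W	5.73	-2.67	-0.07	-1.96	-0.54
Y	2.08	-0.47	0.07	-1.67	-0.35
V	-5.87	-0.94	0.28	1.10	0.48
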