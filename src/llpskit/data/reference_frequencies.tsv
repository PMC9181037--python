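# Average amino-acid composition of the UniProtKB/Swiss-Prot database
# (release-wide background frequencies, normalized to sum to 1).
# Users may substitute any 20-row table of the same shape, e.g. a
# eukaryote-only or proteome-specific background.
# columns: amino_acid <TAB> frequency
A	0.082574
C	0.013812
D	0.054649
E	0.067261
F	0.038635
G	0.070764
H	0.022720
I	0.059153
K	0.058052
L	0.096587
M	0.024122
N	0.040637
P	0.047443
Q	0.039335
R	0.055350
S	0.066460
T	0.053548
V	0.068662
W	0.011010
Y	0.029226
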