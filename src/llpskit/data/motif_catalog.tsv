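# Default motif catalog: short sequence motifs implicated in protein phase
# separation. Patterns are Python regular expressions over uppercase one-letter
# amino-acid codes.
#
# GAR entries implement RGG/RG repeat units with spacers of up to four
# arbitrary residues between units (Thandapani et al. 2013 Mol Cell
# classification of RGG/RG motifs: Tri-RGG, Di-RGG, Tri-RG, Di-RG).
#
# LARKS entries are a SEQUENCE-PROXY catalog: LARKS are defined structurally
# (kinked beta segments; Hughes et al. 2018 Science), which is out of reach of
# a sequence scanner, so the shipped entries are literal segments crystallized
# from the FUS low-complexity domain. They flag candidate sites only.
#
# Zipper entries are likewise literal steric-zipper-forming segments from the
# amyloid literature (Sawaya et al. 2007 Nature), not an energy-based detector.
#
# columns: name <TAB> class <TAB> pattern <TAB> source
Tri-RGG	GAR	RGG.{0,4}RGG.{0,4}RGG	Thandapani 2013 Mol Cell
Di-RGG	GAR	RGG.{0,4}RGG	Thandapani 2013 Mol Cell
Tri-RG	GAR	RG.{0,4}RG.{0,4}RG	Thandapani 2013 Mol Cell
Di-RG	GAR	RG.{0,4}RG	Thandapani 2013 Mol Cell
LARKS-FUS-37	LARKS	SYSGYS	Hughes 2018 Science (FUS 37-42, sequence-proxy)
LARKS-FUS-54	LARKS	SYSSYGQS	Hughes 2018 Science (FUS 54-61, sequence-proxy)
LARKS-FUS-77	LARKS	STGGYG	Hughes 2018 Science (FUS 77-82, sequence-proxy)
Zipper-GNNQQNY	zipper	GNNQQNY	Sawaya 2007 Nature (Sup35)
Zipper-NNQQNY	zipper	NNQQNY	Sawaya 2007 Nature (Sup35)
Zipper-VQIVYK	zipper	VQIVYK	Sawaya 2007 Nature (tau PHF6)
Zipper-polyQN	zipper	[QN]{6,}	Poly-Q/N amyloid-prone stretch
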