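# llpskit

Per-residue sequence features and whole-sequence summary statistics for
proteins that undergo liquid–liquid phase separation (LLPS).

Phase-separating proteins — FUS, hnRNPA1, TDP-43 and their relatives — are
typically driven by intrinsically disordered, low-complexity regions whose
behavior is encoded in sequence-level patterns: biased composition, charge
decoration, aromatic/π-stacking spacing, and short repeating motifs such as
RGG boxes. `llpskit` turns a protein sequence (plus, optionally, a multiple
sequence alignment and per-residue tracks from third-party structure/disorder
predictors) into a stacked set of per-residue feature tracks and summary
scalars that make those patterns visible and comparable. It is a library
first, with a thin CLI, for computational biologists studying condensate
biology and for anyone curating sequence features of disordered proteins.

## What it computes

**Composition and patterning** — amino-acid frequencies; binary per-residue
tracks and percent contents for polarity (S,T,Y,Q,N,C,M), hydrophobicity
(G,A,V,I,L,P,F), aromaticity (F,Y,W,H), π-system centers (R,N,D,Q,E,G plus
aromatics), charge (H,K,R positive / E,D negative) and side-chain
hydrogen-bonding capability; per-residue enrichment against a background
frequency table (Swiss-Prot average shipped, user-replaceable).

**Complexity** — Shannon entropy in two modes. Window (block) mode:

    S(j, N) = − Σ_aa f_aa · log₂ f_aa

over the amino-acid fractions f_aa inside the length-N window starting at j,
assigned to the window center; residue mode averages S(j, N) over every
window containing a position. Low-complexity regions (LCRs) are called from
the residue profile (entropy below a threshold) or from per-amino-acid
sliding-window enrichment, and overlapping calls are merged into unified
regions with unioned enrichment sets.

**Charge decoration** — with f₊, f₋ the fractions of positive/negative
residues (K,R vs D,E by default; H-inclusive display convention available):

    FCR  = f₊ + f₋
    NCPR = f₊ − f₋
    OCS  = (f₊ − f₋)² / (f₊ + f₋)        (0 when FCR = 0)
    SCD  = (1/N) Σ_{m>n} q_m q_n √(m−n)   (Sawle–Ghosh)

plus the Das–Pappu (CIDER) diagram class and sliding NCPR/FCR tracks.

**Motifs** — regex-catalog scanning with full overlap reporting; GAR
(glycine–arginine-rich) region assembly from Di/Tri-RGG and Di/Tri-RG units;
maximal tandem n-mer repeats with minimal-period reporting. A documented
default catalog ships (RGG grammar, FUS LARKS sequence proxies, steric-zipper
segments); users can supply their own.

**Conservation** — per-MSA-column descriptors projected onto the query:
diversity (distinct residues binned 0–5), strength (column information
content scaled by occupancy, binned 0–5), and chemical character of the
consensus residue.

**Consensus** — parsing of a uniform per-residue prediction dialect
(secondary structure ss3/ss8, solvent accessibility, disorder probability,
contact maps) and order-invariant plurality-vote consensus tracks with
declared tie rules (coil / medium / disordered / no-contact).

## Worked example

The package bundles the 526-residue human FUS sequence (UniProt P35637), the
classic LLPS model protein:

```
$ llpskit report --fasta src/llpskit/data/fus_P35637.fasta --out fus_demo
fus_demo.features.tsv
fus_demo.summary.json
fus_demo.regions.bed
```

Selected values from `fus_demo.summary.json`:

```
aromatic_percent      10        polar_percent   40
hydrophobic_percent   42        charged_percent 17
fcr    0.167    ncpr  0.027     ocs 0.004   scd 0.539
cider_class  weak polyampholyte/polyelectrolyte
n_gar  3       lcr_coverage_percent  64
```

Reading: FUS is 40% polar and only 17% charged, with a slight positive
excess (NCPR +0.027) and nearly symmetric charge (OCS ≈ 0.004) — a weak
polyampholyte on the CIDER diagram. About two-thirds of the sequence sits in
low-complexity regions, and exactly three glycine–arginine-rich (GAR/RGG)
regions are detected, all in the RNA-binding C-terminal part (starting at
residue 213): the signature architecture of a prion-like N-terminal domain
plus an RGG-studded C-terminus. Per-residue tracks are in
`fus_demo.features.tsv`; region calls, in BED-like 0-based half-open
coordinates, are in `fus_demo.regions.bed`.

The same stages are available individually (`llpskit compose | entropy |
charge | motifs | conserve | consensus`) and as library functions
(`llpskit.analyze_sequence`, `llpskit.shannon_residue`, `llpskit.scd`, ...).

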