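# Methods

This note documents the statistics `llpskit` computes, the conventions and
defaults it adopts where the field leaves a choice open, and what the test
suite does and does not establish.

## Coordinates, alphabet, validation

All coordinates are 1-based inclusive, matching how protein regions are
reported in the literature; BED-like exports convert to 0-based half-open
and say so in their headers. Sequences are validated to the 20 standard
amino acids plus `X`; the ambiguity codes B/Z/J/U/O are folded into `X` with
a logged warning rather than rejected, so records from real databases parse.
`X` counts toward length and every fraction denominator but never matches a
class, a motif, or an entropy letter category — this keeps fractions
comparable across records at the cost of slightly deflating feature
densities in `X`-rich sequences.

## Physicochemical classes

The class sets (polar S,T,Y,Q,N,C,M; hydrophobic G,A,V,I,L,P,F; aromatic
F,Y,W,H; π-system R,N,D,Q,E,G ∪ aromatic; positive H,K,R; negative E,D) are
the groupings standard in LLPS sequence analysis. Glycine is deliberately
both hydrophobic and a π-system center (peptide-bond π electrons); histidine
is both positive and aromatic. The "charged" summary uses the union
{H,K,R,E,D}. Side-chain hydrogen bonding is not settled nomenclature; the
defaults are donors {R,K,W} (N–H only), acceptors {D,E} (carbonyl O only),
both {S,T,Y,N,Q,H}, and all class sets can be overridden from a TSV file.
Percent summaries round half away from zero to whole percents; raw
fractions are always retained alongside.

## Shannon-entropy complexity

Block mode computes S(j,N) = −Σ f_aa log₂ f_aa over the 20 standard letters
with denominator N, assigned to the window center j + ⌊(N−1)/2⌋ (left-biased
for even N — a deterministic convention). Residue mode averages the block
values over every window fully inside the sequence that contains the
position; near the termini fewer than N windows exist and the mean is over
the available ones only, avoiding padding artifacts. The default window
N = 12 sits inside the 5–20 range appropriate for compositional effects.

LCR calling from the residue profile uses threshold 2.2 bits, extends each
sub-threshold run by half a window on each side (the positions whose windows
overlap the run), and annotates residues reaching an in-region frequency of
0.30. The enrichment-based caller uses window 20 (the upper end of the
compositional range, favoring contiguous regions over speckle) and a
sliding-window fraction of 0.45. Merging unions regions that overlap or are
separated by at most max_gap = 10 residues and unions their enrichment sets;
it is idempotent, and a merged region's mean entropy is the length-weighted
average of its parts (a display approximation, not recomputed from the
profile). These thresholds are defaults for exploration, not published
constants: on FUS they reproduce the known picture — G-rich low-complexity
zones at ≈156–263, 373–425 and 450–511, S/Q-rich stretches in the prion-like
domain, nothing inside the folded RRM — but exact LCR boundaries are
tool-dependent everywhere in this field and are treated as qualitative.

## Charge decoration

Two residue-set conventions are exposed. Display tracks ("patterning")
count histidine as positive ({H,K,R} / {E,D}). The decoration scalars —
FCR, NCPR, OCS, SCD and the diagram class — default to {K,R} / {D,E}
("decoration"), the convention of the CIDER framework, so values are
comparable with the charge-decoration literature; His inclusion is a flag.
OCS at FCR = 0 is defined as 0 (the symmetric, continuous limit of the 0/0
form). SCD is evaluated over charged positions only, which is algebraically
identical to the naive double loop; the tests verify agreement to 1e-9.
Note that SCD is even in the charges (it sums q_m·q_n products), so it is
invariant under both sequence reversal and global charge inversion; NCPR is
the quantity that flips sign under inversion. Terminal and backbone charges
are ignored (sequence-only model); kappa and pH-dependent ionization are out
of scope. The Das–Pappu regions use the published boundaries: FCR < 0.25
weak, 0.25–0.35 Janus, above that strong polyampholyte unless one sign's
fraction exceeds 0.35 while the other does not (strong polyelectrolyte).

## Motifs

The scanner reports every overlapping match by restarting the search one
position after each match start; tests verify equivalence with a
try-every-start brute-force matcher. GAR regions are built from Di-/Tri-RGG
and Di-/Tri-RG units with inter-unit spacers of up to 4 residues, merged
when separated by ≤ 25 residues. Neither parameter has a published value;
these defaults follow the RGG/RG motif classification literature and yield
the three expected GAR regions on FUS (all downstream of the prion-like
domain), which constrains but does not uniquely fix them — both are
configurable. LARKS and steric-zipper catalog entries are literal sequence
proxies for structurally defined motifs and are labeled as such in the
catalog; they flag candidate sites, nothing more. Tandem-repeat detection
reports maximal runs of a non-periodic unit repeated ≥ 3 times, suppressing
rotated-phase duplicates (a run strictly contained in a longer run of the
same period) so a GGQ·6 run is reported once with unit GGQ.

## Conservation

Diversity bins the number of distinct residues in a column (gaps and X
excluded): 1→0, 2→1, 3→2, 4→3, 5–6→4, ≥7→5. Strength discretizes column
information content: IC = (log₂20 − H) × occupancy, binned as
⌊6·IC/log₂20⌋ clipped to [0,5], with occupancy the fraction of rows carrying
a real residue. A flat background is used — no background frequencies and no
pseudocounts by default (a pseudocount flag exists) — so strength is a
contract-level reproduction of HMM-logo-style 0–5 scores, not a value-level
match to any particular logo tool. One consequence of the linear binning:
level 5 is reached by any column with IC ≥ 5/6·log₂20, so in alignments
with more than ~5 rows an extremely skewed two-residue column (e.g. 5:1)
also scores 5; the "only perfect columns score 5" reading holds exactly for
small alignments (≤5 rows, verified exhaustively in the tests) and
approximately otherwise. Character takes the most common residue (ties to
the alphabetically lowest, logged) and resolves overlapping class
memberships by the fixed precedence other(G,P) → charge → aromatic → polar
→ π-system → hydrophobic, so G/P report as "other" and H as "charge".
All-gap or all-X columns yield missing values, not zeros.

## Consensus

The consensus operator is a per-position plurality vote, chosen for being
simple, order-invariant and idempotent, with declared tie rules: coil for
secondary structure, medium for burial, disordered for disorder, and
no-contact for contacts (which require a strict majority). A disorder score
of exactly 0.5 is classed disordered (ordered is strictly below 0.5). The
ss8→ss3 collapse is the standard H,G,I→H; E,B→E; T,S,C→C. Contact maps are
symmetrized by the pairwise maximum before voting and masked at sequence
separation < 3 to avoid trivial near-diagonal contacts. Predictors are
weighted equally; calibrating between predictor score scales is explicitly
out of scope.

## Synthetic data

The generators produce uniform or composition-biased random sequences,
embedded homopolymer blocks, and random predictor tracks. They emulate the
shape of real inputs (alphabet, dialects, probability ranges), not their
biology: no positional correlation, no domain architecture, no evolutionary
signal. Tests built on them establish algorithmic correctness — bound
respect, oracle agreement, invariances, tie-rule behavior — and say nothing
about predictive performance on real proteins. The real-sequence anchor in
the suite is the bundled canonical FUS (P35637) fixture, whose composition,
segment NCPR values, tyrosine partition and GAR count are checked end to
end. Problem sizes in the checks (≤ 300-residue sequences for the SCD
oracle, 1,000 windows for entropy bounds, 100 seeded track sets for
consensus) were chosen to exercise the algorithms thoroughly while keeping
the default suite fast.

## Known limitations

- LCR boundaries and GAR parameters are qualitative defaults; different
  published LCR tools disagree on exact boundaries and this package does not
  arbitrate between them.
- LARKS/zipper detection is sequence-proxy only; structural motif detection
  requires structure prediction, which is out of scope.
- Conservation strength is a self-defined 0–5 information measure, not a
  reimplementation of any specific logo tool's normalization.
- Disorder/secondary-structure/accessibility consensus requires
  user-supplied predictor output; the package never runs predictors.
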