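# Methods

This note documents the models, parameters and design choices behind
srnakit, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic validation does and does not show.

## Read cleaning and accounting

Reads are modelled as insert + 3′ adapter (+ filler when shorter than the
read length).  The 3′ adapter is located at the leftmost position where
the adapter prefix explains the entire remaining tail of the read with at
least 6 nt of overlap and at most one mismatch; no published algorithm is
attached to the original accounting categories, so this rule is the
package's own and both thresholds are configurable.  Categories are made
disjoint by a fixed assignment order: polyA (insert ≥ 90% A) → 5′-adapter
contaminant (insert begins with the first 8 nt of the 5′ adapter) → no 3′
adapter → empty insert → shorter than 18 nt → clean.  Inserts longer than
30 nt are counted as "no 3′ adapter": no usable adapter position yields a
plausible small-RNA insert.  Reads are accepted as-is (`High_quality`
equals the read total); no base-quality model is used, since quality
filtering in this workflow family is reported without a stated algorithm.

Trimming is exact and idempotent on generator reads because the generator
refuses to plant inserts that themselves contain an adapter-like match; on
arbitrary reads an insert can, with small probability, contain a 6-nt
adapter-prefix match by chance, and re-trimming would then shorten it.

## Energy model and folding engine

Secondary structures and duplexes are scored with a compact
nearest-neighbour model: Watson–Crick plus G:U pairs, a 6×6 stack table of
Turner-style ΔG°37 values shipped as `data/stack_energies.tsv` (flip
symmetry is asserted at load time), size-dependent hairpin / bulge /
internal-loop penalties with 1.75·RT·ln extrapolation beyond tabulated
sizes, an affine multiloop cost (3.4 + 0.4 per branch), and a minimum
hairpin loop of 3 nt.  Internal loops are capped at 30 unpaired nt
(structures beyond the cap are inadmissible, in the dynamic program and in
the explicit loop-decomposition energy alike).  Folding is a Zuker-style
O(n³) recursion compiled with numba; tie-breaking prefers the 5′-most
pairing, so output is deterministic.  The model is intentionally simpler
than a full Turner 2004 parameterization (no dangles, no terminal-AU
penalties, no coaxial stacking): the thresholds used downstream
(ΔG ≤ −18 kcal/mol, MFEI > 0.85) are model-relative, and the synthetic
truth is constructed under this same engine, so every threshold is
meaningful by construction.  The engine is validated against exhaustive
enumeration of all pseudoknot-free structures for sequences up to 14 nt.

Hybridization energies use the same stack and loop tables with a duplex
initiation cost of +4.1 kcal/mol, intermolecular pairs only, and loops
between consecutive pairs capped at 6 unpaired nt — large interior loops
contribute nothing to short small-RNA duplexes.  The empty duplex has
energy 0, so reported duplex MFEs are never positive.  Validation is
against exhaustive enumeration of all monotone pair chains for 15-nt pairs.

## Novel miRNA prediction

Eligible tags are the unannotated, intronic and antisense-exonic mapped
tags with at most 10 genomic hits.  Windows are the tag spans ±150 nt,
merged per strand when overlapping, and a window must carry at least 3
supporting reads (a desk-scale guard against singleton degradation reads;
configurable).  Evaluation excises a flank-bounded region centred on the
most abundant tag of the window, so that arbitrarily long merged windows
fold the same local context.  From the window fold, the mature's pairing
partners define the star span with the Dicer 2-nt 3′ overhang; the
mature..star-spanning slice is re-folded on its own, and the seven
criterion flags (mature in one arm — ≥ 60% of mature bases paired, none
internally; star inside the window and disjoint from the mature; no
unpaired run > 4 nt within the mature:star duplex — the threshold is a
package choice, as "large" is not quantified in this workflow family;
precursor ΔG ≤ −18 kcal/mol; MFEI > 0.85; mature length 20–22 nt;
mature:star duplex < −20 kcal/mol) are computed on that precursor.  The
two ΔG thresholds are applied at the stages where each belongs: −18 to the
folded precursor, −20 to the mature:star hybridization of the final call.
A candidate without star-supporting reads is still reported, at tier
"candidate" rather than "high": star absence lowers confidence but does
not reject.

## The exact count test

With a single library per condition there is no replicate dispersion to
estimate; the appropriate exact null for "same relative abundance" is
conditional: given the total x + y of a miRNA across the two libraries,
y ~ Binomial(x + y, N₂/(N₁+N₂)) where N₁, N₂ are the clean-read totals.
The two-sided P doubles the smaller inclusive tail and is capped at 1;
x = y = 0 gives P = 1.  This test is symmetric in the two libraries and
monotone in |x − y| at fixed total.  Zero counts are replaced by a 0.01
pseudo-NE only for ratio/fold-change computation, never for the test.
Benjamini–Hochberg is the default adjustment (Bonferroni available), and
the significance call requires adjusted P < 0.01 *and* a beyond-2-fold NE
ratio — both explicit configuration, since published significance
thresholds for this design are rarely stated.

## Target rules

The duplex model for target scanning is ungapped: the six rules index
fixed miRNA positions, which presupposes no bulges, so bulged sites are
out of scope.  G:U wobbles count 0.5 toward the weighted totals (rules on
mismatch *counts*) but are treated as non-mismatches for the adjacency and
position rules, which speak of mismatches as events.  The "perfect"
reference for the 75%-of-MFE rule is the miRNA's exact Watson–Crick
complement hybridized with the same duplex engine.  The rule engine is
validated against an independent recount over every ≤3-edit variant of a
perfect 21-nt site.

## Synthetic data generator

The generator emulates the structure of a two-condition small RNA-seq
experiment at desk scale: a 2 × 100 kb genome; 40 known miRNAs with a
mature/precursor reference (precursors carry 5 nt of genomic context so
templated isomiRs remain inside them); 30 unannotated hairpins for
prediction; 20 decoy loci cycling through rRNA/tRNA/snRNA/snoRNA/repeat/
exon/intron; and two ~10⁵-read libraries.  Planted hairpins are built from
a stem-loop template (complementary arms, 10–14 nt AT-rich loop, 1–2 point
changes in the arm opposite the mature so the mature maps to exactly one
locus) and rejection-sampled until the candidate evaluator itself accepts
them on the exact windows the pipeline will build — recovery experiments
therefore have a well-defined positive truth.  Mature lengths are drawn
from {20, 21, 22} with probabilities 0.15/0.30/0.55, giving the
characteristic insert-length mode at 22 nt, and first nucleotides are U
with probability 0.8, reproducing the 5′-U bias of real mature miRNAs.

Expression means are scaled so clean reads fill the nominal library size
(10⁵).  Twelve known miRNAs carry a planted 4-fold change (six up, six
down, baseline mean 150 before scaling — well above the ≥ 50 counts where
the exact test has power); the remainder are null with log-uniform means.
Known-miRNA reads carry single-base edits (rate 0.05, uniform position,
uniform alternative base) or templated end offsets (rate 0.15, offsets in
±2 weighted toward 3′ variation), mutually exclusively; every emitted read
records its category, source and variant in a per-read truth table.
Contaminant categories are mixed in at fixed fractions (2% missing
adapter, 1% empty insert, 1% 5′ contaminant, 2% short, 0.1% polyA) plus
0.2% genome-background degradation reads.  Read qualities are constant;
sequencing error beyond the planted single substitutions is not modelled.
All randomness derives from one integer seed; regeneration is
byte-identical.

What passing recovery tests show: the pipeline's operations invert the
generator's planted structure exactly under this energy model — they do
not show that the fixed thresholds are optimal for real libraries, where
adapter chemistry, expression skew, non-templated additions and
cross-mapping are all harsher than the simulation.

The negative control for novel prediction is an Altschul–Erickson-style
dinucleotide-preserving shuffle of each chromosome (Eulerian walk with a
composition-preserving remainder); planted reads no longer map, so any
prediction on the shuffled genome would be a false positive of the
criteria themselves.

## Numerical and degenerate-input choices

Sequences are stored internally in the DNA alphabet; U is accepted
everywhere on input and RNA is emitted in reports.  Coordinates are
0-based half-open internally and 1-based inclusive in rendered tables.
Folding requires ≥ 10 nt; the MFEI of a GC-free sequence is NaN and fails
the MFEI criterion.  Tags matching several matures are assigned to the
placement with the smallest total end offset (known matching) or to the
mature with higher expression, then lexicographically first name (edit
detection) — collisions are broken deterministically.  Traceback
re-derives DP decisions with a 10⁻⁷ tolerance and a fixed option order.
Manifests contain versions, seeds and sha256 checksums but no timestamps,
so identical runs are byte-identical.

## Known limitations

Exact mapping only (no mismatched or gapped alignment); non-templated 3′
additions fall into the unannotated pool; A-to-I inference against the
genome is not attempted; no replicate-aware dispersion modelling; target
scanning has no accessibility or conservation term.  Problem sizes in the
test-suite recovery experiments (60 kb / 20 k reads for unit fixtures,
2 × 100 kb / 10⁵ reads for the default study conditions) were chosen so a
full validation runs in minutes on a single core.
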