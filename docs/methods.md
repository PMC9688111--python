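# Methods

This note records the models, conventions and numerical choices behind
`tbmevo`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Motif grammar and scanning

The scanner recognises three tankyrase-binding-motif (TBM)
configurations, stated with 1-based positions:

| name      | length | constraints                          |
|-----------|--------|--------------------------------------|
| canonical | 8      | R at 1, one of {A,C,G,P} at 4, G at 6 |
| rx4       | 8      | R at 1, G at 6                       |
| rx5       | 9      | R at 1, G at 7                       |

The `Rx(n)Gxx` notation counts *n* wildcards between the arginine and
the glycine; this fixes the geometry above as the only self-consistent
reading, and makes every canonical window also an rx4 window.  A window
is reported once, labelled with the most specific grammar it satisfies
(`canonical ≻ rx4 ≻ rx5`).  Because the rx4 and rx5 windows differ in
length, one arginine can anchor both an 8-mer and a 9-mer hit; both are
reported.  Overlapping windows all count.  The ambiguity residue `X`
never satisfies a constrained position (a motif call should not rest on
an ambiguous base call) but is accepted at wildcard positions.

## Correspondence with the human motif

Positional homology is taken from the multiple sequence alignment.  The
reference map assigns the k-th non-gap column of the reference row to
residue k; a hit in an ortholog is

* `canonical_aligned` / `relaxed_aligned` when its arginine occupies
  exactly the column of the reference arginine (split by configuration),
* `nearby_unaligned` when the arginine is within ± `nearby_window`
  columns (default 30),
* `absent` otherwise; species with no row are `no_ortholog`.

When several hits qualify, the best verdict wins.  The column window is
a deliberately simple proxy for "a possible motif in the disordered
neighbourhood of the human site": no disorder predictor is consulted,
and the window size is configurable and recorded in the output
provenance block.  Enlarging the window can only improve a verdict,
never worsen it (a property the tests assert).

The packaged curated binder table carries 26 reference TBMs across 22
partner proteins, verbatim from the underlying catalogue, including the
7-residue USP25 entry, which is stored with a `truncated` flag because
the canonical grammar needs 8 positions; scanning a full-length USP25
sequence is left to the user.  Axin1's non-canonical second motif is
excluded — its binding rules are unclear, so no grammar can be stated
for it.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignments use
affine gap costs in the Gotoh three-state formulation: a gap of length
L costs `open + L·extend`, i.e. the first gapped residue pays
open + extend.  End gaps are penalized in global mode.  Transitions
between the two gap states are allowed, so a gap in one sequence may
directly follow a gap in the other (never a gap aligned to a gap).
Defaults are BLOSUM62 with open 10 / extend 0.5 (global) and
open 14 / extend 4 (local), the defaults of the EMBOSS tools these
functions replace; `X` scores 0 against everything.  Traceback
tie-breaks are fixed (substitution state preferred over a gap in the
second sequence, over a gap in the first), so alignments are
reproducible.  Percent identity divides by the full alignment length
including gap columns (the EMBOSS "Identity" convention); a
shorter-sequence denominator is available behind a flag and reports
name the convention used.

The test suite checks both aligners against an exhaustive enumeration
oracle (plain memoized recursion over all alignments; for local
alignment, the maximum over all substring pairs) on short sequences
over a 4-letter alphabet with harsh mismatch scores — the regime where
adjacent opposite-strand gaps can beat substitutions.

## Conservation profiling

Per column the profile reports the number of distinct non-gap residue
identities (`X` counts as its own symbol), the gap fraction, and a 1–9
grade: diversity counts are banded into nine equal-width bins over
[1, max diversity observed], with 9 the least diverse.  This grade is a
transparent, model-free surrogate for Bayesian phylogeny-aware rate
grades: it uses only the column composition, so it is exactly
reproducible, but it ignores tree structure and sequence weighting —
closely related over-sampled clades inflate apparent conservation.
Columns gapped in the reference are excluded rather than reassigned to
neighbouring residues.  A residue is *strictly conserved* when its
column shows a single non-`X` identity and no gaps; only those residues
are meant for projection onto structures (written into the PDB B-factor
column, two decimals, all other bytes preserved).

Pairwise identity from an MSA counts identical non-gap matched columns
over the columns where at least one of the two rows is non-gap;
columns gapped in both rows carry no information about the pair and are
excluded from the denominator.

## Distances, neighbor joining, bootstrap

Distances from an MSA are p-distances over columns where both rows are
ungapped, optionally Poisson-corrected (`−ln(1−p)`); saturated pairs
(p ≥ 0.95) are capped at a configured maximum (default 10
substitutions/site) to keep matrices finite.  Poisson correction, not a
JTT maximum-likelihood distance, is the default: at the problem sizes
this package targets the claim under test is topology recovery, which
the simpler model supports, and the substitution is recorded in run
metadata.  ML tree search is out of scope.

Neighbor joining is the classical Saitou–Nei agglomeration on the
Q-criterion with a lowest-index tie-break and negative branch lengths
clamped to zero; the result is an unrooted tree with a trifurcating
root.  On additive matrices the tree's path lengths reproduce the input
to numerical precision (asserted at 1e-9 on random 6-taxon matrices).

Bootstrap resamples alignment columns with replacement from one seeded
generator; each internal edge of the full-data tree is annotated with
the percentage of replicate trees containing the same bipartition
(consensus trees are not built).  Identical seed and input give
byte-identical Newick output.

## The simulator

`simulate_family` emulates the statistical structure the comparative
analysis relies on, not biological realism:

* **Tree** — a Yule (pure-birth) tree, or a user-supplied Newick;
  branch lengths are rescaled so the root-to-tip height equals
  `tree_height` (default 0.4 substitutions/site at rate multiplier 1).
* **Architecture** — ordered blocks of `domain` and `linker` kind.  The
  default blueprint is a ~400-residue miniature of a multi-domain
  protein: four domains (rate multiplier 0.25) separated by three
  linkers (rate 2.0, indel rate 0.1/site), mirroring the observation
  that inter-domain linkers are the least conserved regions.
* **Substitutions** — Poisson events per site with uniform exchange
  over the 20-letter alphabet.  Uniform exchange (not an empirical
  matrix) keeps background motif-hit rates analytically tractable:
  a canonical window occurs with probability (1/20)·(4/20)·(1/20).
* **Indels** — only in linker blocks (this mirrors the disordered
  linkers of real proteins and keeps motif coordinates stable);
  insertions and deletions each at half the block's indel rate, with
  geometric lengths (p = 0.5).  Every residue carries a persistent
  homology token, so the emitted alignment is the true one by
  construction.
* **Planted motifs** — written into the root; constrained positions
  are protected from substitution and deletion, wildcards evolve
  freely (so scanners must handle diverged wildcards); in taxa outside
  the designated subset the arginine is ablated to a random non-R
  residue.  The truth table records presence, residue position and
  alignment column per (taxon, motif).

Passing tests on simulator output therefore demonstrate pipeline
correctness — coordinate bookkeeping, column correspondence, verdict
logic, tree recovery — under the generator's assumptions.  They do not
demonstrate robustness to real-data features the generator omits:
alignment error (the simulator emits the true alignment), non-uniform
amino-acid composition, rate variation within blocks, positive
selection, or assembly artefacts in transcriptome-derived sequences.

## Problem sizes and determinism

The shipped checks use desk-scale inputs chosen to exercise every code
path: 1,000 random sequences (length ≤ 300) for scanner–oracle
equivalence; 250 random pairs (length ≤ 8, 4-letter alphabet) for the
aligner oracles (60 for the O(n⁴) local oracle); 50 random additive
6-taxon matrices for NJ; 100 bootstrap replicates on a two-clade
4-taxon family; 20 six-taxon families for planted-motif recovery; and
40 motif-free families (5 × 400 residues each) for the background hit
rate.  Every random draw derives from an explicit seed; randomized CLI
subcommands refuse to run without one.

## Known limitations

* The conservation grade is composition-based; it is not comparable
  numerically to phylogeny-aware grades, only rank-wise similar.
* The "nearby" verdict is a column-window heuristic; it neither knows
  about disorder nor about compositional context.
* The global aligner penalizes end gaps; tools that default to free
  end gaps will differ on sequences of very different lengths.
* p/Poisson distances ignore among-site rate variation; deep
  divergences will be compressed relative to ML distances.
* No automated screen for low-quality or mis-assembled input sequences
  is provided; such filtering is left to the user's curation.
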