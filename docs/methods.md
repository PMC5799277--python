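# Methods

## Descriptor variables

A secondary structure is a sequence plus a nested (pseudoknot-free)
base-pairing map. Four variables summarise it:

1. **loop %** — 100 × (unpaired nucleotides) / n;
2. **external-loop %** — 100 × (nucleotides in terminal loops) /
   (unpaired nucleotides), where a terminal loop is a maximal unpaired run
   closed by a single base pair at a stem extremity (a hairpin loop, *not*
   the exterior unpaired region);
3. **stem GC %** — GC among paired nucleotides;
4. **loop GC %** — GC among unpaired nucleotides.

GC counts treat U as non-GC; N counts toward length and category sizes but
never toward GC, and all descriptors are invariant under T↔U. By default
the GC percentages are relative to the nucleotides of their category
(stems, loops), the literal reading of "GC contents in stems and in
loops"; `gc_denominator="total"` normalises by n instead. The bundled
reference tables are used verbatim and never re-derived, so classification
does not depend on how their source normalised GC (some bundled rows are
not arithmetically reconcilable with either convention; they are data).

Degenerate structures are flagged rather than silently zeroed: with no
paired bases, stem GC and external-loop % are reported as 0 with an
`empty_categories` flag; likewise loop GC with no unpaired bases.

## Built-in folder

The descriptors are defined on *any* dot-bracket structure, so externally
predicted structures (thermodynamic folders, published diagrams) can be
imported as two-line records. The built-in folder is a deterministic
maximum-scoring nested folder in the Nussinov style with a stacking
term: pair scores GC = 3, AU = 2, GU = 1, +1 for each pair stacked
directly on another, minimum hairpin loop of 3 nt. Ties in the traceback
are broken toward the pairing whose opening index is smallest, making the
output unique for a fixed input. It maximises a base-pairing score, not
free energy: it reliably recovers designed stems (and is verified
exhaustively against enumeration of all nested structures at n ≤ 14) but
is not a substitute for thermodynamic prediction on natural RNAs — which
is why the classification pipeline consumes printed descriptor tables or
imported structures rather than refolding.

## Profile comparison and classification

Similarity of two profiles is the Pearson correlation *r* of their
descriptor 4-vectors. With 4 points the t-transform
t = r·√(2/(1−r²)) has 2 degrees of freedom; reported one-tailed
(upper-tail) p-values use that transform, under which r = 0.95
corresponds to p ≈ 0.025. The *decision rule* for significant similarity
is the configurable threshold r ≥ 0.95, kept separate from the p-value so
the two conventions cannot silently disagree. Queries are assigned to the
cluster of the maximal-r reference; ties break by smaller p, then by
reference order, with all tied references reported. Zero-variance
4-vectors yield an explicitly non-comparable result, excluded from
enrichment denominators and listed in reports.

Benjamini–Hochberg adjustment (statsmodels' step-up implementation behind
`bh_adjust`) is applied by default across the full query × reference
matrix of a run — the most conservative natural family, since the family
used by the original analyses is not stated — with a per-query
alternative.

## Swinger rules and detection

The 23 rules are the non-identity permutations of {A, C, G, T}; cycle
type determines the class (9 involutions, 14 asymmetric 3-/4-cycles) and
the canonical name (`X<->Y` swaps sorted alphabetically; cycles written
from their alphabetically first member). Together with the identity they
form the symmetric group S₄, so composition and conjugation stay inside
the set — properties the tests check exhaustively.

Detection uses exact k-mer seeding (k = 12) on the regular genome and the
23 transformed genomes, both strands, with ungapped extension: on each
seeded diagonal the longest window with identity ≥ 0.8 covering ≥ 0.5 of
the read is kept (fewest mismatches, then leftmost, among equal lengths).
The thresholds are the published mapping criteria; the search algorithm
itself is this package's design, since the original analysis used a
commercial mapper whose algorithm is not specified. Reads with a
qualifying hit on the regular genome are classified regular and never
searched further, mirroring the published exclusion order; only hits on
transformed genomes of identity-free reads are swinger calls. Gapped
alignment is out of scope at this version; the noise model of the
simulator is correspondingly substitution-only. Minus-strand hits found
on a Q-transformed genome are reported under conjugate(Q), i.e. the
exchange rule relative to the strand that templated the read; reported
coordinates are 1-based inclusive on the plus strand (internally 0-based
half-open).

## Statistics

Fisher's method sums −2·ln pᵢ over k independent one-tailed tests and
refers the total to chi-square with 2k df. Spearman correlations use
mid-ranks (ties share averaged ranks) and the one-tailed t approximation
with df = n − 2, appropriate at the n = 23 scale of the abundance table;
an exact-permutation option (n ≤ 10) exists mainly as a cross-check.
All one-tailed p-values are upper-tail (positive association), so
negative correlations report p > 0.5.

## Synthetic data

All generators are driven by `numpy.random.default_rng(seed)` and are
bit-reproducible for a fixed configuration.

- **Hairpins.** Rod topology: a random stem arm (with an exact GC count,
  so realised GC lands within 5 points of the target), a ≥ 3-nt loop over
  the non-self-pairing alphabet {A, C}, and the reverse-complement arm.
  Branched: two or more such hairpins joined by short unpaired spacers.
  These emulate the rod vs. branched distinction of viroid-like
  structures, not the sequence statistics of real viroids.
- **Swinger reads.** A uniform-composition toy genome (default 10 kb) and
  reads of 40 nt (near the SOLiD mean of ~36), half swinger-transformed
  and half regular by default, strands drawn uniformly, substitution noise
  at a configurable rate. The truth table records the rule a detector
  should report (the conjugate for minus-strand reads) and the interval.
  A transformed read that coincidentally still matches the untransformed
  genome at the mapping criteria is re-placed: such a read is by
  definition regular and no detector applying the published exclusion
  rule could attribute it to the planted rule. Recovery statistics on
  these simulations therefore measure the detector's behaviour on
  unambiguous planted truth; they do not bound its sensitivity on real
  transcriptomes with repeats, homopolymer errors or colorspace
  artefacts, which are not modelled.
- **Profile clusters.** Cluster centers are drawn uniformly in descriptor
  space and re-drawn until pairwise |r| between center 4-vectors is below
  0.5 — Pearson similarity is location/scale-free, so separation must be
  in vector shape; members and queries add N(0, 2) noise (descriptor
  units) clipped to [0, 100]. Recovery on these sets demonstrates the
  assignment machinery, not the separability of real RNA classes.

## Problem sizes and numerical choices

Default experiment sizes — 1000 reads for recovery runs, 200 random
sequences (n ≤ 14) for folder-vs-enumeration checks, 200 queries for
classifier recovery — are the package's chosen desk-scale settings; each
completes in seconds. Exhaustive enumeration of nested structures is
exponential and guarded to short sequences. Floating-point comparisons in
BH and window-feasibility tests carry 1e-9-scale guards; correlations are
clipped to [−1, 1] before the t-transform.

## Known limitations

- The folder optimises pair + stacking score, not thermodynamics;
  descriptor values for natural RNAs should come from imported structures.
- The detector is ungapped; indel-containing reads lose identity along
  the whole diagonal.
- The bundled reference set carries the printed descriptor values of its
  source tables; the full reference matrix behind the original cluster
  definitions is not public, so cluster assignments against `table1` are
  assignments against *these* 72 labelled profiles, nothing more.
- The per-rule abundance table is validated structurally (23 rows, rule
  names) and through its cross-platform correlations; per-rule read
  counts are platform- and pipeline-specific and are not reproduced.
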