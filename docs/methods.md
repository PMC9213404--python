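# Methods

This note documents the models, conventions and design choices behind
`nrltr`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate, and where behaviour was a genuine
design decision rather than a forced consequence of the problem.

## Read-pair model and discovery

A fragment of mean length 350 bp (sd 35) sequenced from both ends with
150-bp reads maps as a *proper* FR pair when both mates align to one
chromosome with an outer span inside `insert_mean ± 3·insert_sd`.  Four
anomaly classes carry insertion signal: *discordant* pairs (span or
orientation violated), *singletons* (one mate unmapped), *soft-clipped*
reads (≥ 10 clipped bases at a junction) and *unmapped pairs* (both mates
inside the inserted element).  Soft-clip evidence takes precedence over the
proper-span predicate: a clipped read is informative even when its pair
span happens to look proper.

Anchor evidence requires the unanchored mate (or clipped tail) to hit the
LTR library at ≥ 0.80 identity over ≥ 36 bp (mate hits) or ≥ 10 bp (clip
hits, which are positionally exact and matched against a ~600-bp element,
so shorter matches are still specific).  Anchors from reads below mapping
quality 20 are discarded to suppress repetitive-region false anchors.  All
thresholds are config-exposed on `DiscoveryParams`.

## Calling, filter levels and TSDs

Anchors cluster by single-linkage within `insert_mean + 2·insert_sd`
(420 bp by default); a cluster needs ≥ 10 supporting reads to become a
call, and clusters deeper than 10,000 reads are dropped as pile-ups.  The
breakpoint is the midpoint between the innermost 5′-side anchor end and the
innermost 3′-side anchor start.

The evidence tier is 5 plus one bonus each for (a) ≥ 2 anchors on both
sides, (b) ≥ 2 soft-clip reads abutting the breakpoint within 10 bp,
(c) a tight cluster interval (≤ 2 read lengths).  For two-sided clusters
the interval is the innermost-anchor span; for one-sided clusters it is the
spread of that side's anchor stack, which is the only width information
available.  This 5+bonus scheme is a declared re-interpretation of the
8-level convention used by discordant-pair callers; the operational rule it
preserves is that clean two-sided, clip-supported calls score ≥ 7, and the
pipeline's default cutoff keeps exactly those.  Calls within 500 bp are
considered the same insertion; the merge keeps the best call (highest
filter level, then total support, then leftmost) rather than dropping the
whole chain, since dropping all would delete every true call observed
twice.  Sub-threshold calls are flagged, not deleted.

TSD detection formalizes what is usually done by eye in a genome browser:
let L be the modal rightmost aligned position among reads clipped on their
right, R the modal leftmost position among reads clipped on their left,
each mode supported by ≥ 2 reads (one chimeric read must not define a
boundary).  If `L − R + 1 ∈ {4, 5}` the interval [R, L] is the TSD and its
sequence is taken from the reference — never from read bases, so a
sequencing error cannot corrupt a reported TSD.  Mode ties prefer more
supporting reads, then the shorter overlap.

## Junction assembly and reconstruction

Reads aligned within 150 bp of the TSD feed the 5′ or 3′ assembly set by
clip side (right-clipped → 5′, left-clipped → 3′), by position for
unclipped reads, and unmapped mates follow their anchor's strand.  Each
side is assembled by greedy overlap-layout-consensus: duplicate reads
collapse into multiplicity, contained reads into their container, then the
highest-scoring pairwise overlap is merged until none of ≥ 40 bp at ≥ 0.90
identity remains.  Overlap detection is exact suffix–prefix matching with a
gapless shared-kmer diagonal route for mismatched overlaps; because the
error model is substitutions-only, overlaps are gapless and this route is
complete (an end-anchored local-alignment fallback covers the
indel-divergent case, which the default simulations never produce).
Consensus is per-column majority with ties broken A<C<G<T; ties in merge
order are broken on sequence content, which makes the assembly invariant to
input read order.  One caveat of any overlap assembler applies: an overlap
lying entirely inside a tandem repeat array longer than `min_overlap` is
phase-ambiguous.  Greedy best-overlap-first resolves this in practice
(true overlaps between adjacent reads are much longer than any repeat
array at ≥ 30× coverage), but sparse data over long arrays can collapse
array copies.

A contig is a junction contig when one end aligns to the ± 1-kb reference
window around the call and the remaining ≥ 30 bp hit the LTR library at
≥ 0.80 identity.  When the TSD is known, the flank window is clipped at the
TSD boundary before the final alignment, so chance matches between element
bases and the opposite flank cannot drag the junction across the insertion
point; the element boundary in the contig is then anchored on the TSD
coordinate.  The 5′ and 3′ non-reference segments are overlap-merged
(coverage-weighted majority); columns where the two sides disagree are
counted in `overlap_mismatches`, never silently resolved — for a provirus
this is exactly where divergence between its two LTR copies shows up.  The
reported sequence runs TSD-to-TSD inclusive, and a TSD copy is attributed
to a side only when that side's contig actually spans the TSD interval, so
`completeness = both` genuinely means two observed TSD copies.  Non-joinable
segment pairs fall back to the longer single side rather than guessing.
Provirus internal regions are deliberately not assembled from short reads
(unresolvable repeats); the element is typed from its LTR junctions, with
`classify_perv_type` available for long element sequences obtained by other
means.

## Classification

*Progressive alignment*: guide tree from 6-mer distances (average-linkage),
profiles merged by global affine alignment (match +1, mismatch −1, open −4,
extend −1), deterministic throughout.  *K3P*: transitions P and the two
transversion classes Q (A↔T/G↔C) and R (A↔C/G↔T) over columns where both
rows carry an unambiguous base;
`d = −¼ ln[(1−2P−2Q)(1−2P−2R)(1−2Q−2R)]`, with saturated pairs reported at
a ceiling of 5.0 substitutions/site.  *Neighbor joining*: canonical
Q-matrix minimization with name-order tie-breaks; negative branch lengths
are clamped to zero with the deficit moved to the sister branch.  NJ on
plain K3P distances stands in for a full maximum-likelihood search: the
scientifically relevant output is the two-family split (LTR-A vs LTR-B),
which NJ recovers exactly on separable data, and ML-specific quantities
(gamma rates, log-likelihoods) are out of scope.

*U3 boundary*: LTR structure is U3–R–U5 with the TATA box at the U3/R
boundary.  Since no fixed coordinates exist for these elements, U3 is taken
as everything before the first TATAWA motif in the 3′ half of the LTR
(fallback: the first 65%).  This is a convention, config-exposed.

*Repeats and subtypes*: tandem arrays are detected de novo by period (a
seed window extends while the next unit-sized block matches the running
consensus with ≤ 3 mismatches; ≥ 2 full copies make an array).  Major type
B requires both an 18-bp and a 21-bp array in U3; B1/B2/B3 are tiers of the
total 18+21 copy number with boundaries 4 and 6 (a declared convention —
only "copy number varies" is established for real elements).  A-types are
A2 when any 8–15-bp sub-repeat array is present, A1 otherwise; for these
short units the mismatch budget is scaled down (`unit_length // 8`, i.e. 1)
because a 3-mismatch budget on an 8-mer matches random sequence ~3% of the
time per position and would classify noise as A2.  Subtype calls are
orientation-invariant: both strands are scored (TATA found, then repeat
content, with a content-based final tie-break) and the better orientation
is read.

*PERV typing*: best local hit against a typed *pol*-marker panel decides
A/B/C; `unknown` below 0.80 identity, below 50 alignment columns (the best
local alignment between unrelated sequences is typically a short
high-identity stretch, so an identity floor alone is not specific), or when
the top two types tie within 0.5%.

## Synthetic data

The generator emulates the study conditions the pipeline is designed for:
150-bp paired-end reads from ~350-bp fragments at configurable coverage
(default 50×), elements of 550–760 bp (default 600, bracketing the observed
~598–710 bp range of real non-reference LTRs including TSDs), insertions
flanked by 4–5 bp TSDs copied from the reference, events ≥ 2 kb apart,
provirus internals of 7 kb (a convention — only the long-PCR product size
range is known for real loci).  Fragment lengths are truncated at ± 3 sd so
the simulator's truth class labels coincide exactly with the discovery
module's classifier on error-free data.  Truth alignments are computed by
mapping each read's donor interval back through the insertion events:
junction-spanning reads become soft-clipped records with the clip at the
junction, reads needing < 20 aligned bases are unmapped, and unmapped reads
keep their raw sequencing orientation as a real aligner would emit them.
All randomness flows from explicit integer seeds; outputs are
byte-identical across runs.

Label-consistent LTR construction: random background occasionally contains
chance TATAWA motifs, chance 18/21-bp arrays, or chance sub-repeat arrays
that would contradict an A-type label.  The generator scrubs these
deterministically (one targeted substitution per offending motif/array,
sparing the designed features), so a spec's subtype label holds by
construction and generator→classifier round trips are exact.  The cohort
generator derives family members from two ancestors by seeded substitutions
(~3%), sparing repeat arrays and the TATA box.

What the synthetic data does **not** emulate: indel and structural
sequencing errors, quality-score distributions, alignment ambiguity in
genomic repeats, GC bias, or a real reference genome's repeat landscape.
Passing tests therefore demonstrate the correctness of the algorithms under
the stated read model, not performance on real whole-genome data, where
aligner behaviour and genomic repeats dominate the error budget.

## Evaluation conventions

Calls match truth one-to-one, greedily by breakpoint distance within 10 bp
(≈ 2 TSD lengths; config-exposed).  Precision is undefined (not 0) when no
calls were made.  TSD exactness requires interval and sequence to equal the
planted target site.  Reconstruction identity compares against the planted
TSD-to-TSD sequence (1.0 means byte-identical).  Cross-sample locus merging
reuses the 500-bp call-merge window; a merged locus sits in the both-TSD
section when any sample observed both copies.

## Problem sizes

The default verification scale — chosen as the smallest scale at which
every stage is exercised with realistic redundancy — is a 2-Mb genome with
20 insertions at 50× for the end-to-end checks, 200–300 kb for unit-level
fixtures, 50 seeds × 5 subtypes for round trips, and a 21-member cohort for
the phylogenetic split.  All are seeded; the acceptance script re-runs them
from scratch.

## Known limitations

* Insertions closer than the merge window (500 bp) collapse into one call;
  the generator's 2-kb spacing reflects this design envelope.
* Tandem arrays longer than `min_overlap` are phase-ambiguous for the
  assembler at low coverage (see above).
* One-sided loci reconstruct partially (`5p_only`/`3p_only`) and are not
  subtype-classified by the pipeline.
* Genotyping (het/hom) and multi-sample joint calling are out of scope;
  per-sample results are combined downstream by the locus summarizer.
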