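# Methods

This note documents the models and procedures implemented in
`rrnppminer`, the parameters that matter, the design decisions that were
genuinely open, and what the synthetic corpus does and does not emulate.

## Regulator detection with a generic profile HMM

The RRNPP families targeted here (Rgg, ComR, PlcR, PrgX) share one
architecture — an N-terminal helix-turn-helix domain followed by a
TPR-repeat peptide-binding domain — which is what makes a *single*
generic profile workable across families.

**Profile construction.** Match states are the bait-alignment columns
with gap fraction ≤ 0.5. Match emissions are column residue frequencies
blended with the Robinson–Robinson background by a total pseudocount
mass of 1 (spread proportionally to the background). Transitions come
from the observed gap structure of the alignment with add-one
smoothing. Insert states emit the background, so inserted residues are
score-neutral.

**Search.** Scoring is log-odds against the background. The decoder is
a local Viterbi over a plan7-like state graph: uniform entry into any
match state (probability 1/M), free exit from any match state, free
flanking target residues. The delete chain allows the alignment to skip
model positions at a cost. Column posteriors come from forward–backward
over the same graph; because every path shares the null-model factor
for unaligned residues, posteriors computed from odds scores equal true
posteriors. Forward and backward totals agree to 1e-6 (checked), and
Viterbi ≤ forward always.

**E-values.** We fit a Gumbel law by maximum likelihood
(`scipy.stats.gumbel_r.fit`) to the Viterbi bit scores of 1,000 random
sequences drawn from the background composition (default length 350),
then report `E(s, D) = D·exp(−λ(s−μ))` with `D` = number of proteins
searched. The calibration seed is recorded. On 1,000 fresh null
sequences about one is expected at `E ≤ 1`, which the suite verifies as
a calibration sanity bound.

**Hit filtering.** `E ≤ 1e-5`, alignment start ≤ model position 10,
model coverage ≥ 90% — all inclusive. Coverage is defined on the
match-state span, pairing naturally with the start-position rule.

**Column masking.** A match column is retained when the mean posterior
over the hits aligning through it is ≥ 0.85. This operationalizes
"high-consensus-posterior columns" with real probabilities rather than
a display glyph encoding; the threshold is configurable.

## Clustering and classification

Hits are projected onto retained columns; pairwise identity is
identical residues over mutually non-gap columns (0 when no such column
exists). Clusters are connected components of the identity graph with a
strict `> 0.90` edge rule (a `>=` switch exists, since both phrasings
appear in common use). Components are ordered by size then smallest
member, making the partition deterministic.

Each cluster's representative is aligned to every bait
(`Bio.Align.PairwiseAligner`, local, BLOSUM62, gap open 11 / extend 1).
The best bait is the highest-**scoring** alignment — ranking by raw
identity is unsound because a short perfect fragment (e.g. a conserved
15-residue cap at 100% identity, 6% coverage) would outrank a
full-length 73%-identity homolog; score ranking matches the "closest
blastp match" convention. Identity < 40% sets the `-like` flag on the
subfamily label. Cluster identifiers are
`subfamily[_like]_{scope}_{k}_` where scope is a species token
(`Sthermo`, `Ssali`, `Svesti`) for single-species clusters and
`gp_sali` otherwise, with one global running counter.

Context genes (any CDS overlapping ±2 kbp of a regulator) are clustered
by all-against-all local alignment with edges requiring a
Karlin–Altschul E-value ≤ 1e-3 (gapped BLOSUM62 parameters λ = 0.267,
K = 0.041) and ≥ 70% coverage of *both* sequences.

## Short-CDS detection and confidence

Candidates are all spans from an allowed start codon (ATG/GTG/TTG) to
the first in-frame stop, 7–60 aa, enumerated on the forward sequence
and on the reverse complement with exactly the same model, which makes
predictions strand-symmetric to the last bit. The confidence is the
two-class posterior

    confidence = π·L_C / (π·L_C + (1−π)·L_B)

with `L_C` the codon-usage likelihood (terminal stop codon uniform over
the three stops; an internal stop codon is scored with a vanishing
probability, since it contradicts the coding hypothesis) and `L_B` an
order-2 Markov chain trained on whole genome sequence, both
Laplace-smoothed; `π = 0.5` by default so the decision threshold of
0.01 acts purely on the likelihood ratio. The genome-wide HMM used in
earlier literature is replaced by this per-ORF posterior deliberately:
it has the same statistical content for fixed candidate spans and is
directly testable. Nested ORFs sharing a stop keep the longest
passing candidate. Neighborhood restriction keeps candidates whose span
intersects `[hit.start − 300, hit.end + 300)` (any overlap counts;
clamped at the contig start).

## AIP annotation

SHP-likeness is a 5-flag score: length 20–26 aa; Lys within the first
four residues; ≥ 5 consecutive C-terminal residues with positive
Kyte–Doolittle hydropathy (Gly tolerated, since mature SHPs end in
Gly-rich tails); C-terminal Gly; and a D/E in the C-terminal half that
is not the final residue. Classification order: a known-AIP seed match
(global alignment identity ≥ 40%) transfers the seed class; otherwise a
flag score ≥ 3 calls SHP. The score-≥ 3 policy is artifact policy, not
a literature constant: it passes every characterized SHP precursor we
encode while random peptides reach it rarely (null simulation in the
suite).

The mature SHP is the suffix starting at the **last** D/E in the
**C-terminal half** of the precursor. The C-terminal-half restriction
exists because several precursors carry acidic residues near the N
terminus (position 2 of MEKVSKILPILILVMDIIIIVGG, for instance) that are
not cleavage sites; the rule reproduces all eight D/E-initial
experimentally observed mature forms. Precursors whose mature form does
not begin with D/E (Cys-initial CIYTIVGGV, leaderless LCP peptides,
MutS-type matures) are *declined* (`None`) and left to a per-cluster
override — guessing with the acidic rule would be wrong more often than
helpful. Gene orientation (divergent / convergent / co_upstream /
co_downstream) is computed from strand and midpoint geometry and is
invariant under reverse-complementing the contig.

## Repertoire analytics

The repertoire matrix is binary presence/absence (paralogs within one
cluster count once). Profile distance is the Hamming count over cluster
columns; the mean is over unordered distinct strain pairs (a
with-replacement convention differing by (n−1)/n is available).
Strain ordering uses average linkage on Hamming distances (the linkage
choice is ours; nothing in the underlying analyses pins it down) with
strains pre-sorted by id for deterministic ties. Trees for cluster
representatives use neighbor joining on `1 − identity` distances with
midpoint rooting — an explicit stand-in for approximate-ML
reconstruction, adequate for ordering and group display but not for
branch-support claims.

## Peptide chemistry

GRAVY is the mean Kyte–Doolittle value per residue, reported at 2 dp.
Monoisotopic masses are built from atomic masses (H 1.0078250319,
C 12, N 14.0030740052, O 15.9949146221, S 31.97207069); peptide mass =
residue masses + one water; `m/z = (M + Δ + z·proton)/z` with the
proton at 1.00727646688 Da. Modification deltas are signed elemental
changes: one intramolecular C–C/C–S crosslink loses H2 (−2.01565 Da),
two crosslinks lose H4 (−4.03130 Da, shared by the two-crosslink
peptides), and the enteropeptin-type modification (Arg →
N-methyl-ornithine plus a crosslink) loses N2H2 (−30.02180 Da).
Carbamidomethylation of Cys (+57.02146 Da) is available as a named
modification for alkylated samples, off by default. Reported rounding
follows print precision: GRAVY 2 dp, deltas 5 dp, m/z 4 dp. One
caveat: for the mature sequence EGIIVIVVG the Kyte–Doolittle mean is
2.42, while a value of 1.91 (equal to that of EGIIVIGVG) circulates in
a published table; we treat that as a suspected transcription error and
exclude the peptide from reference checks.

## The synthetic corpus

The generator emulates the statistical structure the pipeline relies
on, with a complete ground-truth manifest. Defaults: 20 genomes
(8 + 7 + 5 across the three species labels) of 200 kbp each, 5 planted
regulator clusters, within-cluster identity 0.95, between-cluster
≤ 0.70, AIP planting rate 0.9, decoy ORFs at 0.2/kbp, coding density
≈ 0.5, low-GC (0.34) order-2 intergenic background distinct from the
A/T-biased codon usage of coding regions. Generation plus the full
pipeline runs in well under two minutes on one CPU.

Design points worth knowing:

- **Family relatedness.** The four family prototypes descend from one
  ancestral sequence (identity 0.55), and substitutions throughout the
  regulator hierarchy avoid the 15 terminal residues. This encodes the
  shared-fold premise (a generic profile only makes sense for
  homologous families) and the conserved terminal domains that make
  full-profile alignment a structural property of true homologs. With
  independent prototypes or uniformly placed mutations, minority-family
  hits would erratically fail the start ≤ 10 / coverage ≥ 90% filter —
  a generator artifact, not a detector property.
- **Coupled composition.** Planted genes are back-translated with the
  configured codon usage, deliberately matching the composition model's
  assumptions; the manifest-recovery tests therefore measure the
  pipeline under its own model, not robustness to model misfit.
- **Guarded ORFs.** Unannotated planted genes (AIPs, decoys) carry an
  immediately upstream in-frame stop so the start-to-first-stop frame
  reproduces planted coordinates exactly — real intergenic DNA is
  likewise stop-saturated.
- **Clean background.** Background segments are rejection-sampled so no
  reading frame contains a planted AIP precursor.

What the generator does **not** emulate: indels and site-rate
heterogeneity in regulator evolution, horizontal transfer,
pseudogenes, annotation errors, genuine RBS signals, and compositional
heterogeneity along real genomes. Passing the recovery tests therefore
demonstrates correctness of the algorithms under their stated
assumptions, not field performance on RefSeq data; the interfaces for
real data (GenBank parsing, bait alignments, seed FASTA) are exercised
separately by round-trip tests.

## Numerical choices

- DP kernels run in natural-log space (numba-compiled); scores are
  reported in bits. The reporting floor is `E ≤ 10`; forward–backward
  posteriors are computed only for reported hits.
- `mutate_protein` substitutes an exact count of positions
  (`round(L·(1−identity))`), replacements drawn from background
  frequencies excluding the original residue, so realized identity is
  deterministic given the position draw and recorded to 3 dp.
- Identity denominators: mutually non-gap retained columns for hit
  clustering (recorded per pair); aligned residue pairs for local bait
  alignments; `max(len)` for global seed matching.
- Ties in clustering order break on lexicographically smallest member;
  cluster naming is a pure function of (subfamily, species set, counter
  state).
- NJ branch lengths clipped at 0 (tiny negative estimates are a known
  NJ artifact); midpoint rooting via scikit-bio.

## Limitations

- The built-in search engine has no multi-domain hit splitting, no
  glocal mode and no acceleration heuristics; it is exact but O(L·M)
  per target, sized for corpora of thousands of proteins, not millions.
- E-values assume the Gumbel tail fits Viterbi scores of i.i.d.
  background sequences; compositionally biased real proteomes would
  need a bias correction the engine does not implement.
- The per-ORF confidence ignores overlapping-gene context and RBS
  strength; on real genomes the 0.01 threshold is permissive by design
  and downstream AIP screening carries the specificity burden.
- Cluster naming reproduces the *scheme*, not the exact published
  identifiers, which depend on the original input ordering.
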