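# rrnppminer

Genome mining of **RRNPP quorum-sensing regulators** and their
**auto-inducing peptides (AIPs)** in streptococci — with the peptide
chemistry needed to chase the mature peptides by mass spectrometry.

Gram-positive bacteria communicate with small secreted peptides that are
re-imported and bind cytoplasmic receptors of the RRNPP superfamily
(Rap, Rgg, NprR, PlcR, PrgX and relatives). In the salivarius group of
streptococci (*S. thermophilus*, *S. salivarius*, *S. vestibularis*),
Rgg-type regulators paired with short hydrophobic peptides (SHPs)
control biofilm formation, competence and the production of radical-SAM
modified peptides (RaS-RiPPs) such as streptide. Finding these systems
in genomes is awkward: the regulators are diverse, and the peptide genes
are tiny (7–60 codons) and usually unannotated.

`rrnppminer` implements the complete mining workflow for people studying
peptide quorum sensing in these (and similar) genomes:

1. **Regulator detection** — a single generic profile HMM built from a
   multiple alignment of experimentally validated bait regulators
   (shared HTH + TPR-repeat topology), searched against proteomes with a
   local Viterbi decoder. Per-target E-values come from a
   maximum-likelihood Gumbel fit to scores of random background
   sequences: `E(s, D) = D · exp(−λ(s − μ))`. Hits are kept when
   `E ≤ 1e-5`, the alignment starts at profile position ≤ 10 and covers
   ≥ 90% of the model.
2. **Similarity clustering** — hits are projected onto high-posterior
   match columns (forward–backward posteriors, mean ≥ 0.85) and grouped
   into connected components of the >90%-identity graph; each cluster is
   classified by its closest bait (Smith–Waterman, BLOSUM62, gap 11/1;
   identity < 40% earns a `-like` signifier) and named with the
   species-scoped scheme (`SHP/Rgg_Sthermo_6_`, `Rgg-like_gp_sali_1_` …).
3. **Short-CDS / AIP discovery** — candidate ORFs of 7–60 aa on both
   strands are scored with a two-class posterior (codon-usage coding
   model vs. order-2 Markov background); candidates with confidence
   ≥ 0.01 within ±300 bp of a regulator are screened against known AIP
   seeds and the SHP sequence grammar (20–26 aa, N-terminal Lys,
   hydrophobic C-terminal stretch, C-terminal Gly, central Asp/Glu), and
   the mature SHP is predicted as the suffix starting at the last
   acidic residue in the C-terminal half of the precursor.
4. **Repertoire analytics** — strain × cluster presence/absence
   matrices, per-species prevalence, distinct repertoire profiles, mean
   pairwise Hamming profile distance, average-linkage strain ordering
   and neighbor-joining trees with midpoint rooting.
5. **Peptide chemistry** — Kyte–Doolittle GRAVY indices, monoisotopic
   masses, modification mass deltas from elemental losses (e.g. −2.01565
   Da for one C–C/C–S crosslink), monocharged m/z and ppm-tolerance peak
   matching.
6. **Synthetic corpora** — a generator that plants regulator homologs at
   controlled identities, AIP genes, context genes and decoy ORFs into
   synthetic genomes, with a ground-truth manifest, so the whole
   pipeline is testable without downloading anything.

## Worked example

```python
from rrnppminer import synthetic_data as sd, pipeline
from rrnppminer.peptide_chem import gravy, mz, modification_delta

cfg = sd.SyntheticConfig(
    rng_seed=5,
    genome_length=50_000,
    n_genomes_per_species={
        "Streptococcus thermophilus": 2,
        "Streptococcus salivarius": 2,
        "Streptococcus vestibularis": 1,
    },
)
genomes, manifest, baits, seeds = sd.generate_corpus(cfg)
result = pipeline.run_pipeline(genomes, baits, seeds, calibration_seed=7)

print(f"{len(result.filtered_hits)} regulator hits in {len(genomes)} genomes")
for c in result.clusters:
    print(f"{c.cluster_id:28s} {len(c.members)} members  "
          f"best bait {c.best_bait} ({c.bait_identity:.0f}% id)")

reg = result.clusters[0].members[0]
cand = result.aip_candidates[reg][0]
print(f"AIP near {reg}: class {cand.aip_class}, {cand.orientation}, "
      f"mature {cand.mature_form}")
print(f"GRAVY({cand.mature_form}) = {gravy(cand.mature_form):.2f}")
print(f"[M+H]+ of DIIIIVGG = {mz('DIIIIVGG'):.4f}")
print(f"streptide crosslink delta = {modification_delta('H2'):.5f} Da")
```

prints

```
10 regulator hits in 5 genomes
SHP/Rgg_gp_sali_1_           3 members  best bait bait1_SHP-Rgg (74% id)
ComS/ComR_gp_sali_2_         3 members  best bait bait21_ComS-ComR (75% id)
PapR/TprA_gp_sali_3_         2 members  best bait bait26_PapR-TprA (73% id)
SHP/Rgg_Sthermo_4_           1 members  best bait bait2_SHP-Rgg (73% id)
SHP/Rgg_Sthermo_5_           1 members  best bait bait3_SHP-Rgg (74% id)
AIP near SYN001_r1: class SHP, co_downstream, mature DIIIIVGG
GRAVY(DIIIIVGG) = 2.24
[M+H]+ of DIIIIVGG = 799.4924
streptide crosslink delta = -2.01565 Da
```

Every hit, cluster, AIP class, mature form and orientation here matches
the generator's ground-truth manifest exactly. To mine real genomes,
read them with `sequence_io.read_genbank` (RefSeq `_genomic.gbff` flat
files), supply your own bait alignment via
`profile_hmm.read_bait_alignment` and AIP seeds via
`aip_annotator.read_seed_fasta`, and call `pipeline.run_pipeline` the
same way.

## Layout

| module | contents |
| --- | --- |
| `sequence_io` | GenBank/FASTA/TSV I/O, 0-based half-open coordinates, table-11 translation |
| `profile_hmm` | profile construction, Viterbi/forward–backward engine, Gumbel E-value calibration, hit filtering, column masking |
| `hit_clustering` | pairwise identity, connected-component clustering, bait classification, cluster naming, 2-kbp context-gene clustering |
| `short_cds_finder` | composition-model training, ORF enumeration, confidence scoring, neighborhood scan |
| `aip_annotator` | SHP grammar flags, mature-form prediction, seed matching, gene-orientation calls |
| `repertoire_analytics` | presence/absence matrices, prevalence, profile statistics, hierarchical ordering, NJ + midpoint rooting |
| `peptide_chem` | GRAVY, monoisotopic masses, modification deltas, m/z, peak matching |
| `synthetic_data` | corpus generator and ground-truth manifest |
| `pipeline` | end-to-end orchestration |
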