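# Methods

This note documents the models, estimator conventions and design choices
behind `fawstrain`, and what the synthetic-data tests do and do not show
about real field data.

## Biological setting and assumptions

The fall armyworm host strains are modeled as two populations fixed for
alternative alleles at one diagnostic exon SNP per marker segment, with the
C-strain carrying much less standing variation than the R-strain (the
consequence of repeated demographic bottlenecks in corn monoculture) and
the R-strain closer to the ancestral pool. Markers sit on the Z chromosome:
females (ZW) are hemizygous and always yield clean haploid sequences; males
(ZZ) carry two Z copies and, when the copies differ anywhere in the
sequenced segment, direct Sanger reads are ambiguous. The workflow's
exclusion rule therefore acts on sequence ambiguity, not on sex: any IUPAC
ambiguity code disqualifies the whole sequence.

Host plant is an imperfect strain label — R-strain larvae are regularly
collected in corn — so the package keeps three parallel strain calls per
specimen (host, phylogenetic clade, diagnostic SNP) and quantifies their
correspondence instead of assuming any one is truth.

## Sequence handling

- Marker alignments are equal-length, gap-preserving (gap-only columns are
  retained so 1-based segment coordinates stay stable), restricted to a
  window of the segment with a column map so the diagnostic site remains
  addressable.
- The host→class mapping ships the survey vocabulary (corn, sorghum,
  cotton → C; turf grasses, pasture grasses, rice, millet, alfalfa → R) and
  is loadable from TSV so new plants can be added without code change.
  Unknown plants raise; they are never guessed.
- Default segment layouts (UBCie695 695 bp, site Ue199 C/T; TpiEI194
  194 bp, site e5[183] C/T; nesEI533 533 bp, site n299 T/C) place each
  diagnostic site inside an exon block with an adjacent indel-prone intron.
  The exon/intron block coordinates are nominal package defaults — segment
  definitions are plain dataclasses and should be overridden when exact
  assay coordinates are known. Diagnostic-site names are interpreted as
  1-based positions in the segment's own frame.

## Distances, trees, supports

- **TN93 distance**, computed pairwise from the two transition proportions
  (purine P1, pyrimidine P2), the transversion proportion Q and base
  frequencies pooled over the pair. Sites with a gap or ambiguity in either
  sequence are removed first (*pairwise deletion* — it preserves signal on
  indel-rich introns). A non-positive logarithm argument marks saturation;
  a saturated pair is a flagged non-finite result and a hard error at the
  matrix level. The implementation is cross-checked in the tests against an
  independently coded closed form and against `ape::dist.dna(model="TN93")`
  (frozen value).
- **Neighbor-joining** follows the Saitou–Nei Q-criterion with two
  determinism guarantees: ties are broken by the lowest pair of original
  taxon indices, and negative branch lengths are clamped to zero with the
  deficit moved to the sibling edge (raw values kept in a `raw_length`
  annotation). NJ is exact on additive matrices; the tests verify this on
  100 random 6–10 leaf trees.
- **Bootstrap** resamples alignment columns with replacement (gap columns
  travel with their column). Support of an internal edge of the reference
  tree is the percentage of completed replicates containing its
  bipartition; a bipartition in a replicate counts only when its edge
  length is positive, since an NJ resolution of an exact tie carries no
  signal — hence identical-sequence alignments give all-zero supports
  rather than artifacts of deterministic tie-breaking. Replicates with a
  saturated pair are skipped and counted (`n_skipped_replicates`); at this
  package's divergence scales the path is unreachable. Default B = 100 in
  tests; B = 1000 available via configuration.
- **Likelihood**: Felsenstein pruning under TN93 (rate matrix normalized to
  one expected substitution/site), vectorized over sites, gaps marginalized
  as missing data. Under this reversible model the likelihood is invariant
  to root placement (asserted to 1e-8 in tests). Maximum-likelihood
  analysis is approximated as NJ start + greedy first-improvement **NNI**
  hill climb with branch lengths held fixed; `max_rounds` caps accepted
  moves and the log-likelihood trace is non-decreasing by construction.
  Base frequencies are empirical; α_R and α_Y are fitted on the start tree
  by coordinate-wise golden-section search with β normalized to 1. This
  deliberately trades search breadth for determinism and desk-scale cost;
  exhaustive heuristic search as performed by interactive phylogenetics
  suites is out of scope.
- **C-strain clade**: over every internal node of the rooted ingroup, the
  tip set maximizing F1 against the C-host labels (ties: larger clade, then
  earlier preorder node). This is an explicit operationalization of what is
  usually done by inspection — the selected clade is monophyletic by
  construction, and its purity (fraction of the clade on C hosts) and
  recall (fraction of C-host tips captured) are reported rather than
  asserted.

## Population statistics

- Complete deletion *within each analysis group* (for Fst/Dxy: the pooled
  population pair): columns with any gap/ambiguity in the group are removed
  before counting. This mirrors the convention of the classic diversity
  software and deliberately differs from the pairwise deletion used for
  tree distances.
- Hd = (n/(n−1))(1 − Σ pᵢ²) over haplotype frequencies; π = the unbiased
  mean over all C(n,2) pairs of the per-site difference proportion.
- **Fst** is the Hudson-style 1 − Hw/Hb with Hw the *unweighted* mean of
  the two within-population mean pairwise differences (group sizes in this
  design are similar) and Hb the mean difference across populations. The
  estimator may be negative by sampling — small negative values on
  within-strain comparisons are expected behavior, not errors. Hb = 0 is
  reported as Fst 0 with a degeneracy flag.
- **Dxy** is uncorrected (no multiple-hit correction): the mean per-site
  difference over all between-population pairs.
- Group tests: Welch's unequal-variance two-tailed *t* (groups of zero
  variance are flagged degenerate: p = 1 on equal means, the p → 0 limit
  otherwise); one-way ANOVA with Tukey HSD using the Tukey–Kramer
  adjustment on unbalanced groups; the compact letter display assigns
  letters from maximal cliques of the non-significance graph at α = 0.05.
- Estimator choices are echoed in every report's provenance block so
  alternates can be compared downstream.

## The synthetic cohort generator

A founder/resampling model, not a coalescent — sufficient to realize the
structure the analysis assumes at O(n) cost:

- Per segment, an ancestral sequence spawns `r_pool_haplotypes` (default
  12) R-strain founder lineages, each site mutating with probability θ/2
  (θ_intron = 0.04, θ_exon = 0.008, so two lineages differ at ≈ θ per
  site). The C-strain pool descends from a C ancestor carrying
  `strain_divergence` (default 0.04) substitutions/site on the shared
  founder branch — this common branch is what makes the C clade
  monophyletic and the diagnostic SNP linked to it — and is bottlenecked to
  `c_founders` (default 2) lineages. Each pool is fixed for its strain's
  diagnostic allele. With equifrequent founders these defaults put Hd(C)
  near 0.5 and Hd(R) near 0.9, reproducing the field asymmetry
  qualitatively (the realized means on 100 seeded cohorts are printed by
  `scripts/acceptance.py`).
- Founder indels: with probability 0.25 per intron block per haplotype, a
  1–10 bp run is gapped out (sequences stay aligned). In heterozygous
  males a gap-length mismatch acts like a frameshifted trace: everything
  downstream of the lesion is emitted as `N`.
- Specimens fill a (continent × host class) collection table; the default
  sizes are the field survey's (252/82/111/166). With probability
  `host_misassignment_rate` (default 0.05) the specimen's host label is
  discordant with its true strain — the label moves, the sequence never
  does. Females draw one haplotype, males two (male fraction 0.5, a
  natural sex ratio); differing male draws produce IUPAC codes and the
  truth table records draws, differences and usability exactly.
- One global seed; every per-segment stream is derived from it by fixed
  offsets, so identical seeds give byte-identical output files.

What passing synthetic tests show: the estimators and the tree stage
recover a planted two-strain structure of realistic effect size under the
stated noise sources. What they do not show: robustness to real-data
features the generator omits — within-segment recombination, migration or
admixture gradients, PCR/sequencing error, alignment error, length
polymorphism beyond simple deletions, and selection within strains.

## Problem sizes

Stochastic suites run on scaled-down cohorts — 100 seeds at 20 specimens
per collection cell for the diversity/Fst recovery rates, 10 seeds at 15
per cell for tree-based clade-vs-host correspondence, 24 taxa at B = 100
for the planted-clade bootstrap — chosen so the whole suite runs on a
laptop core in well under a minute per property while keeping binomial
noise far from the asserted margins. The generator's scientific defaults
(collection sizes, rates, effect sizes) are never changed by tests; only
cohort counts scale.

## Known limitations

- The NNI hill climb refines topology only; branch lengths stay at their
  NJ values, so reported ML trees are likelihood-ranked topologies rather
  than fully optimized estimates.
- The marker-discovery stage models the "insect-annotated" provenance
  filter as a boolean GFF3 attribute; reproducing the original annotation
  cross-referencing requires external databases and is out of scope.
- Candidate ranking among genes passing all filters is a greedy rule by
  within-strain variable-site count with > 1 Mb spacing — an explicit
  stand-in for a selection step the original workflow performed by
  inspection.
- Real-survey row-level values (per-comparison Fst/Dxy, per-tree Hd/π)
  require the deposited GenBank sequences; the pipeline ingests such data
  when supplied but no test or script depends on downloads.
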