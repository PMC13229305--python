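# fawstrain

Analysis toolkit for validating **Z-linked host-strain markers** in the fall
armyworm (*Spodoptera frugiperda*). FAW consists of two morphologically
indistinguishable populations — the **C-strain** (collected from corn,
sorghum, cotton) and the **R-strain** (turf and pasture grasses, rice,
millet, alfalfa) — that can only be told apart molecularly. `fawstrain`
implements the full marker-validation workflow for exon+intron segments of
three Z-chromosome loci (*UBC4* → UBCie695, *Tpi* → TpiEI194, *nes* →
nesEI533), each carrying one strain-diagnostic exon SNP (Ue199, e5[183],
n299). It is aimed at insect population geneticists who assign strains by
any of three routes — collection host plant, phylogenetic clade, or
diagnostic SNP — and want those routes cross-validated with diversity and
divergence statistics.

## What it computes

- **Ingestion and exclusion** — FASTA marker alignments + specimen metadata
  TSV; ZZ males heterozygous anywhere in a segment give ambiguous Sanger
  traces, so any sequence containing an IUPAC ambiguity code is excluded.
- **Phylogenetics** — Tamura–Nei (TN93) pairwise distances with pairwise
  deletion, neighbor-joining with deterministic tie-breaks, column-resampling
  bootstrap, outgroup rooting, Felsenstein-pruning log-likelihood under TN93
  and greedy NNI refinement; the C-strain clade is the monophyletic group
  maximizing F1 against C-host labels.
- **Population statistics** — haplotype diversity
  Hd = (n/(n−1))(1 − Σ pᵢ²), nucleotide diversity π (mean pairwise per-site
  difference), Hudson-style **Fst = 1 − Hw/Hb**, and uncorrected **Dxy**
  (mean between-population per-site difference), all under complete deletion
  within the analysis group; Welch *t*, one-way ANOVA and Tukey HSD with a
  compact letter display.
- **Comparison grid** — per marker, the six (host class × continent)
  population comparisons (CS–RS within and between continents, CS–CS,
  RS–RS), aggregated to grand and per-category means.
- **Marker discovery** — VCF split by strain, biallelic/MAF ≥ 0.05 filter,
  gene-level candidate selection (2 000–7 000 bp, 2–5 introns,
  insect-annotated, variable in both strains, > 1 Mb spacing), and the
  cM = Mb × (cM/Mb) recombination extrapolation capped at 50 %.
- **Synthetic cohorts** — a founder/resampling generator that reproduces the
  structure the analysis assumes: a bottlenecked low-diversity C-strain vs a
  high-diversity R-strain, fixed diagnostic alleles, intronic indels, male
  heterozygote ambiguity, and host misassignment.

## Worked example

```sh
fawstrain simulate demo --seed 11 --scale 0.08   # ~49 specimens, 3 segments
fawstrain analyze demo demo_report --bootstrap 50 --seed 11
```

prints the aggregated divergence grid of the simulated cohort:

```json
{
  "grand_mean_fst": 0.389,
  "grand_mean_dxy": 0.047,
  "category_mean_fst": {"CSCS": -0.071, "CSRS_BETWEEN": 0.617,
                        "CSRS_WITHIN": 0.617, "RSRS": -0.064},
  "category_mean_dxy": {"CSCS": 0.01, "CSRS_BETWEEN": 0.06,
                        "CSRS_WITHIN": 0.06, "RSRS": 0.032}
}
```

Between-strain comparisons (CS–RS) show high relative differentiation
(Fst ≈ 0.62) while the within-strain, between-continent comparisons sit
near zero — strain identity, not geography, structures the cohort. Dxy stays
small throughout: the strains differ by mechanisms that inflate Fst far more
than absolute divergence. `demo_report/` contains the rooted Newick trees
with bootstrap supports, per-specimen strain calls under all three methods,
correspondence tables, diversity and divergence TSVs, and a provenance JSON.

`fawstrain aggregate` (no argument) prints the same aggregation for the
packaged reference grid of the three markers from the Western Hemisphere
field survey: grand mean Fst 0.354, grand mean Dxy 0.057, with CS–RS mean
Fst ≈ 0.50 against within-strain means ≤ 0.10.

## Layout

| module | role |
| --- | --- |
| `fawstrain.seqdata` | FASTA/TSV I/O, host→strain mapping, ambiguity exclusion, alignments |
| `fawstrain.simulate` | synthetic cohort generator + ground-truth tables |
| `fawstrain.phylo` | TN93 distances, NJ, bootstrap, rooting, likelihood, NNI, clade extraction |
| `fawstrain.popstats` | Hd, π, Fst, Dxy, Welch t, ANOVA/Tukey, letter display |
| `fawstrain.markers` | VCF/GFF3 candidate discovery, cM extrapolation, SNP calls, correspondence |
| `fawstrain.pipeline` | orchestration, comparison grid, aggregation, report writing |
| `fawstrain.cli` | `fawstrain simulate / discover / analyze / aggregate` |

See `docs/methods.md` for estimator conventions, simulator assumptions and
known limitations.
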