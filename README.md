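# popstruct

Continental-ancestry assignment and within-group population-structure
analysis for genotype cohorts, plus a synthetic-cohort rehearsal mode with
known truth.

The framework chains, in order:

1. **merge** — intersect two genotype datasets by variant id (duplicate ids
   dropped, swapped/strand-flipped alleles reconciled, mismatches removed,
   all counted in a merge report), concatenating their samples;
2. **LD pruning** — windowed greedy r² pruning (default 50 kb window,
   10 kb step, r² > 0.025), with high-LD region exclusion from a BED file
   and r² computed on a reference sample subset;
3. **supervised admixture** — per-individual ancestry proportions `q`
   against fixed reference allele frequencies `f` by EM on the binomial
   mixture likelihood; continental ancestry group (CAG) assignment at the
   ≥ 80 % threshold;
4. per CAG: **relatedness filtering** (genomic relationship matrix,
   cutoff, greedy unrelated selection), **per-CAG LD pruning**, **PCA**
   (Patterson normalization, projection of related/reference samples,
   iterative 10-PC / 6 σ / 5-iteration outlier removal), scree-elbow
   **top-PC selection**, silhouette-selected **K-means** (k = 2..20),
   **correspondence analysis** of cluster × birth-region labels with a
   chi-square test, and pairwise **Hudson Fst** between clusters with
   min/mean/max summaries and phylip output.

The `synthetic_cohort` module generates hierarchical Balding–Nichols
cohorts (continents at F ≈ 0.1, subpopulations at F ≈ 0.003–0.015,
admixed individuals, parent–offspring pairs, birth-place labels correlated
with subpopulation) so the whole pipeline is testable offline.

## CLI

```bash
popstruct simulate --seed 1 --out cohort_dir            # synthetic cohort + truth tables
popstruct merge a.vcf b.vcf --out merged.vcf
popstruct prune merged.vcf --r2 0.025 --out keep.txt
popstruct admix merged.vcf --reference-labels refs.tsv --out q.tsv
popstruct unrelated merged.vcf --out-prefix rel
popstruct pca merged.vcf --out-prefix pcs
popstruct cluster pcs_scores.tsv --out-prefix km
popstruct ca km_labels_joined.tsv --row-col cluster --col-col birth_region --out-prefix ca
popstruct fst merged.vcf --groups groups.tsv --out-prefix fst
popstruct run-all --config pipeline.yaml                # full framework
popstruct rehearse --seed 1 --out rehearsal_dir         # synthetic end-to-end + truth scoring
```

`run-all` / `rehearse` accept a YAML config (see
`PipelineConfig.from_yaml`); in synthetic mode the config embeds a
`PopulationSpec` describing continents, subpopulations, reference panels,
admixed blocks, related pairs, and label concordance. A manifest
(`manifest.json`) records per-stage parameters and sample/variant counts;
`rehearse` additionally writes `rehearsal_report.json` scoring every stage
against the simulation truth.

## Notes on desk-scale defaults

- The relatedness cutoff in the bundled rehearsal config is 0.1 rather
  than the 0.025 production default: at a few thousand SNPs, GRM entries
  carry sampling noise with SD ≈ 1/√M ≈ 0.01, so the production cutoff
  would flag hundreds of spurious pairs. Parent–offspring pairs sit at
  ≈ 0.5 and are still caught.
- Synthetic SNPs are spaced 20 kb apart by default so that chance LD in
  small reference panels does not dominate window pruning; a dense
  `ld_block` mode exists to exercise the pruner.
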