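# polarfix

Derived-allele fixation calling in a two-species cohort, timing of
fixation against ancient genomes, and ancient-DNA damage QC — packaged
with a fully synthetic study generator so every stage is verifiable at
desk scale.

## What it does

Given per-sample diploid genotype calls (VCF with GT/DP/AD), gene models
(GFF3), a reference (FASTA), sample metadata (TSV) and per-site base
counts for ancient samples (TSV), the pipeline:

1. **Filters** sites: per-individual depth masking (default ≥ 4×),
   biallelic restriction (multiallelic sites excluded), non-synonymous
   coding-effect annotation within candidate genes, and a per-species
   callable-fraction guard. Every site receives exactly one filter fate.
2. **Polarizes** candidates with two outgroup individuals: the ancestral
   allele is the allele both outgroups carry homozygously; any site
   where an outgroup carries the allele fixed in the focal (polar)
   population is removed.
3. **Classifies origin**: fixed derived alleles present in the sister
   (brown) population are standing variation; fixed derived alleles
   absent from sister and outgroups are de novo.
4. **Times fixation** against ancient genotypes: pre-fixed (ancients
   homozygous derived) vs post-fixed (an ancient carries the ancestral
   allele) vs unresolved.
5. **Damage QC**: per-position terminal C→T / G→A deamination profiles
   from reads, plus heterozygote validation with a strict 30%
   minor-base-proportion rule and a read-position rescue check for
   damage-type (C/T, G/A) allele pairs.
6. **Differentiation check**: per-gene dosage PCA (gene ± 50 kb, 95%
   completeness) with a polar/brown separation score.

The `synthetic_cohort` module generates a complete self-contained study
(reference, genes, genotypes, ancient reads with planted terminal
deamination, truth table) whose planted per-gene site classes are the
oracle for recovery testing. The default plan yields 48 fixed derived
sites (34 pre-fixed, 14 post-fixed, 0 de novo) across 7 of 11 genes.

## CLI

```bash
# generate a synthetic study (seed mandatory) + a ready-to-run config
polarfix simulate --outdir study --seed 1

# run everything end-to-end
polarfix run --config study/config.yaml

# or stage by stage (each consumes the previous stage's TSVs)
polarfix filter   --config study/config.yaml
polarfix classify --config study/config.yaml
polarfix time     --config study/config.yaml
polarfix damage   --config study/config.yaml
polarfix pca      --config study/config.yaml
```

Outputs land in the configured `outdir`: `filter_fates.tsv`,
`classification.tsv`, `timing.tsv`, `gene_summary.tsv`,
`damage_profile.tsv`, `het_validation.tsv`, `pca_*.tsv`, a consolidated
`site_report.tsv` (with a flag marking sites where an ancient individual
is not fixed for the derived allele) and a `summary.txt` echoing every
threshold.

All thresholds live in the YAML config: depth (4), callable fraction
(0.9), heterozygote proportion rule (strict > 0.30), terminal window
(5 bp), rescue cutoff (0.5), PCA flank (50 kb) and completeness (0.95),
excluded genes (`EDH3` by default).

## Layout

```
src/polarfix/
  models.py            core domain types (samples, gene models, site calls)
  io_formats.py        FASTA/GFF3/VCF/TSV readers and writers
  annotation.py        depth mask, allelic state, coding effect, filter cascade
  polarity.py          outgroup polarization, fixation, origin classes
  timing.py            pre/post fixation against ancient genotypes
  damage.py            deamination profiles + heterozygote validation
  pca.py               per-gene dosage PCA and species separation
  synthetic_cohort.py  planted-truth study generator
  pipeline.py          orchestration, stage TSVs, consolidated report
  cli.py               click subcommands
```
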