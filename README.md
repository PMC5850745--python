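# coalabc

Structured-coalescent SNP simulation and approximate Bayesian computation
(ABC) for three-population divergence-with-bottleneck demographic models,
with the variant-filtering and population-genetic statistics needed to take
a SNP panel from VCF to divergence-time estimates.

The package supports two input paths:

- **real data**: a VCF of biallelic SNP genotypes plus a two-column
  sample-to-population map (and optional GFF3/BED annotation for
  neutral-site selection);
- **self-contained**: synthetic genotype matrices generated under the same
  demographic models, so the entire pipeline runs and is testable offline.

## What it does

| module | role |
| --- | --- |
| `coalabc.variant_io` | VCF/GFF3/BED I/O, five-step SNP filter chain (GQ/DP masking, biallelic, per-individual and per-site missingness, MAF), neutral/genic/intermediate site classification |
| `coalabc.popgen_stats` | nucleotide diversity, Tajima's D, Weir–Cockerham F<sub>st</sub>, 100-kb binned scans, Gabriel-style haplotype blocks with N50, and the fixed-order ABC summary-statistic vector |
| `coalabc.demography` | the three competing origin models (`mesoamerican`, `phi`, `protovulgaris`: which deme evolved at constant size while the others were founded through bottlenecks), prior specification and sampling |
| `coalabc.coalescent_sim` | structured Kingman coalescent, MAF-ascertained SNP dropping, multi-chromosome dataset simulation, balanced/resumable ABC reference tables |
| `coalabc.abc_engine` | rejection / multinomial-logistic / neural-network model choice, Bayes factors, rejection posteriors with 95% CI and 95% HPD, leave-one-out cross-validation (Epred) |
| `coalabc.synthetic_data` | pseudo-observed bundles with known truth, planted-defect toy VCFs and annotation fixtures with independently-derived expected outcomes |
| `coalabc.cli` | the `coalabc` command-line pipeline |

## CLI

Every run is driven by a YAML config with a mandatory master seed; identical
config + seed reproduces every artifact bit for bit.

```bash
coalabc example-config > config.yaml   # template to edit
coalabc simulate --config config.yaml  # build the ABC reference table
coalabc observe  --config config.yaml  # filter VCF / synthesize, compute stats
coalabc choose   --config config.yaml  # PP + Bayes factors per method
coalabc infer    --config config.yaml  # parameter mean / 95% CI / 95% HPD
coalabc cv       --config config.yaml  # cross-validated prediction error
coalabc full     --config config.yaml  # all of the above
coalabc make-fixtures --out-dir fx --seed 3
```

Reference tables are streamed to TSV in chunks and a partially written table
is resumed from its last complete row; `simulate --paper-scale` switches the
default scaled-down budget to the full 1,010,101-simulation design (slow).

## Conventions

- Positions and annotation intervals are 1-based inclusive internally; BED
  input is converted at the parsing boundary.
- Missing genotypes are excluded, never imputed, from all frequency
  computations.
- One coalescent generation is equated to one calendar year, so event times
  are interchangeable between generations and years.
- Chromosomes are fully linked internally and independent of one another;
  SNPs are ascertained conditional on a pooled minor-allele frequency
  threshold (default 0.05), which absorbs the mutation rate.
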