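# hypwas

Hierarchical phenome → genome association toolkit. The pipeline links
hyperspectral reflectance phenomics to genomics in two tiers:

1. **Band selection ("HypWAS")** — plot-level reflectance spectra are
   trimmed, rebinned and smoothed, reduced to genotype-level BLUPs by a
   multi-environment mixed model, and screened against a response trait by
   cross-validated recursive feature elimination (0–100 importance scale).
2. **GWAS per selected band** — three engines over SNP dosages:
   - `mlm` — mixed linear model with VanRaden kinship and structure
     covariates (P3D-style variance reuse, optional exact per-marker refit),
     BH-FDR significance;
   - `farmcpu` — iterative fixed/random scan with pseudo-QTN covariates,
     genomic binning and REM-likelihood bin/QTN selection, BH-FDR;
   - `svr` — ε-SVR variable-importance scan (permutation importance or
     linear |weight|), significance by a permutation-based global empirical
     threshold controlling family-wise error at α.
3. **Post-GWAS** — peak flanking regions (default ±150 kbp, merged when
   overlapping), LD decay with half-max summary, allelic effects, and
   GFF3 gene-interval overlap.

A first-class `simulate` module generates genotypes with tunable positional
LD (Gaussian-copula AR chain), spectra with planted SNP→band signals, and
balanced multi-environment trials with known variance components, so every
stage is testable without external data.

## Test

```sh
python -m pytest -q tests/
```

One acceptance test (`test_criterion_2_deposited_genotype_accounting`)
requires an externally deposited genotype file and fails when offline unless
the file is cached at `data/deposited_genotypes.hmp.txt`.

## CLI

```sh
# synthetic dataset
hypwas-pipeline simulate --config sim.yaml --out sim/

# individual stages
hypwas-pipeline preprocess --spectra sim/spectra.tsv --keep 395:1005 --width 10 --savgol 11:2 --out pre.tsv
hypwas-pipeline blup --pheno sim/phenotypes.tsv --trait yield --out blup.tsv
hypwas-pipeline hypwas --bands blup_bands.tsv --trait blup.tsv --seed 1 --out rfe/
hypwas-pipeline gwas --method svr --pheno blup.tsv --geno sim/genotypes.hmp.txt --perms 200 --alpha 0.05 --out gwas.tsv
hypwas-pipeline postgwas --result gwas.tsv --geno sim/genotypes.hmp.txt --gff genes.gff3 --window 150000 --out post/

# full pipeline from a YAML config (see hypwas.cli.PipelineConfig fields)
hypwas-pipeline run --config cfg.yaml
```

Pipeline spectra files key each row as `<genotype>:<environment>:<replicate>`
so per-band BLUPs can be fit from the spectra file alone.

## Layout

| module | contents |
|---|---|
| `hypwas.simulate` | `SimConfig`, genotype/spectra/trial generators, ground truth |
| `hypwas.spectra` | `SpectraMatrix`, trim/rebin/Savitzky–Golay/PCA outlier screen |
| `hypwas.phenostat` | `PlotTable`, REML/BLUP mixed model, heritability, correlations |
| `hypwas.rfe` | recursive feature elimination, importance scaling (band selection) |
| `hypwas.geno` | HapMap/VCF I/O, MAF filter, imputation, kinship, structure PCs |
| `hypwas.gwas_mlm` | mixed-linear-model scan |
| `hypwas.gwas_farmcpu` | iterative fixed/random pseudo-QTN scan |
| `hypwas.gwas_svr` | SVR importance scan + global empirical threshold |
| `hypwas.postgwas` | FDR, flanking regions, LD decay, allelic effects, gene overlap |
| `hypwas.cli` | `hypwas-pipeline` entry point and pipeline orchestration |
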