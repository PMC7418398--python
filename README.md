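# pqtlkit

A toolkit for genome-wide protein quantitative trait locus (pQTL) mapping
from DIA proteomics and SNP genotypes, built as a tested, reusable
pipeline:

1. **Absolute quantification (`pqtlkit.tpa`)** — total-protein-approach
   concentrations (pmol per mg input protein) from peptide-level MS2 peak
   areas, with shared-peptide signal redistributed to carrier proteins in
   proportion to their unique-peptide totals.
2. **Genotype QC (`pqtlkit.qc`)** — call-rate / MAF / exact
   Hardy-Weinberg filters (0.99, 0.01, 1e-4), sliding-window LD pruning
   (50/5/0.8), and genotype PCA with outlier flags.
3. **pQTL scan (`pqtlkit.scan`)** — per-(variant, protein) additive OLS
   adjusting for gender, ethnicity and the top 3 genotype PCs; a single
   genome-wide threshold (alpha / #SNPs, e.g. 0.05 / 1,671,387 = 2.99e-8);
   local/distant classification at 1 Mb from the gene body.
4. **Hotspots (`pqtlkit.hotspots`)** — Spearman co-expression matrix and
   a seed/extension algorithm grouping neighboring pQTLs of correlated
   proteins (< 1 Mb seeds, |rho| > 0.5), majority annotation, and a
   Fisher test of shared hotspots among correlated pairs; reusable on
   external eQTL tables.
5. **Region enrichment (`pqtlkit.regions`)** — mapping of variants to
   regulatory regions (BED) and gene features (GTF: UTR/CDS/exon/intron),
   with per-(gene, feature) Fisher enrichment under Bonferroni control.
6. **Trait integration (`pqtlkit.traits`)** — rsID joins against
   variant-trait catalogs and LD (r² > 0.8) + conditional-analysis
   colocalization against eQTL/GWAS summary tables.
7. **Synthetic data (`pqtlkit.simulate`)** — a seeded generator for
   genotypes (Gaussian-copula LD blocks), proteomes with planted genetic
   and covariate effects, peptide tables that round-trip exactly through
   the quantification equations, and annotation/trait/eQTL files — so the
   whole pipeline is testable offline with known ground truth.

Small-sample tests (HWE exact, Fisher 2x2 up to n=500) are evaluated in
exact rational arithmetic (`pqtlkit.exact`) so they agree with
enumeration oracles to float precision.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(threshold worked example, TPA round trips, statistical-engine oracles,
scan calibration/recovery, hotspot recovery, colocalization recovery,
end-to-end reproducibility).

## CLI

```bash
# generate a synthetic study with planted effects
pqtlkit simulate --config sim.yaml --out study/

# individual stages
pqtlkit quantify --peptides study/peptides.tsv --meta study/protein_meta.tsv --out quant/
pqtlkit qc --vcf study/genotypes.vcf --out qc/ --call-rate 0.99 --maf 0.01 --hwe 1e-4
pqtlkit prune --vcf qc/filtered.vcf --out pruned.txt --window 50 --step 5 --r2 0.8
pqtlkit scan --vcf qc/filtered.vcf --proteins quant/protein_matrix.tsv \
    --meta quant/protein_meta.tsv --covariates study/covariates.tsv \
    --out associations.tsv --threshold auto

# everything end to end
pqtlkit run-all --config pipeline.yaml
```

`pipeline.yaml` lists the input paths plus optional `qc:`, `scan:`,
pruning, hotspot and colocalization parameters (see
`pqtlkit.pipeline.PipelineConfig`). Each run writes per-stage TSVs, a
`manifest.json` with versions/seeds/parameters, and a `summary.json`
with headline counts; fixed seeds give bit-identical outputs.

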