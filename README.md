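# melascan

Selection-scan statistics, Hardy-Weinberg/LD analysis, quantitative-trait SNP
association, and power analysis for candidate-gene pigmentation studies —
with seeded synthetic-data generators so the full pipeline can be exercised
and validated end-to-end without external data.

## What's inside

| module | contents |
| --- | --- |
| `melascan.genodata` | data model + IO: VCF/tabular genotypes, TSV phenotypes (melanin index, sex), BED regions, ancestral-allele tables, per-population allele counts |
| `melascan.hwe_ld` | exact Hardy-Weinberg test, expected genotype counts, two-locus EM haplotype frequencies and r² |
| `melascan.popdiff` | Hudson / Weir-Cockerham FST, locus-specific branch lengths, 100 kb / 25 kb sliding-window S, π, Tajima's D and lnRH, genome-wide empirical p-values, per-region significance counts |
| `melascan.wglrh` | long-range haplotype test: core haplotypes, EHH curves, REHH, gamma-MLE null within core-frequency bins, derived-allele (>0.60) filter, Benjamini-Hochberg FDR |
| `melascan.assoc` | additive and unconstrained melanin-index regression with sex covariate, effective-test LD collapse, Bonferroni, allele-count cohort comparison, Wahlund/stratification report |
| `melascan.power` | analytic (noncentral chi-square, plus finite-sample noncentral-F variant) and simulated power for the additive test |
| `melascan.synthsim` | seeded generators: HWE association cohorts, Wahlund mixtures, Balding-Nichols allele-count panels, forward Wright-Fisher sweep haplotypes |
| `melascan.cli` | `melascan` command-line interface |

## CLI

```bash
melascan --show-config                 # print all defaults (INI)
melascan simulate cohort --n 150 --freq 0.5 --beta -1.3 --seed 5 \
    --out-genotypes cohort.vcf --out-phenotypes pheno.tsv
melascan hwe   --genotypes cohort.vcf --out hwe.tsv
melascan ld    --genotypes cohort.vcf --out r2.tsv
melascan assoc --genotypes cohort.vcf --phenotypes pheno.tsv --out assoc.tsv
melascan simulate panel --n-snps 5000 --fst 0.05,0.0,0.0 --out panel.tsv
melascan scan  --counts panel.tsv --pop pop1 --ref-pop pop2 \
    --out-windows windows.tsv --out-lsbl lsbl.tsv
melascan simulate sweep --seed 2 --out haps.tsv
melascan wglrh --haplotypes haps.tsv --out wglrh.tsv
melascan power --freqs 0.1,0.2,0.5 --betas 1.3 --out power.tsv
melascan report --scan-windows windows.tsv --regions genes.bed --out report.tsv
```

Output TSVs carry comment headers recording the package version, a config
hash, and any assumption flags; identical configs give byte-identical data
rows.

## Conventions

- VCF positions are 1-based; BED and all internal window math are 0-based
  half-open.
- Genotype calls count copies of allele_b (the VCF ALT); association and
  frequency operations take an explicit effect-allele argument.
- Windows are anchored at multiples of the step from coordinate 0.
- Diversity statistics computed from array SNPs carry ascertainment bias;
  they are calibrated against the genome-wide empirical distribution rather
  than corrected.
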