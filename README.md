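# c9hap

Haplotype-aware analysis of G4C2 repeat-length data at the *C9ORF72*
locus. The package classifies phased tag-SNP haplotypes into four
groups (ancestral/founder × risk/non-risk), maps unordered repeat-length
pairs from fragment analysis onto those haplotypes with a Bayesian
classifier, and provides the downstream statistics: expansion
enrichment between groups, rank tests on repeat lengths,
Firth-fallback logistic association, and inverse-variance fixed-effects
meta-analysis. A synthetic cohort generator emulates the data model
(including fragment-analysis artifacts and case/control allele-frequency
enrichment) so the whole pipeline is testable without any real
genotypes.

## Modules

| Module | Purpose |
| --- | --- |
| `c9hap.io_formats` | Phased VCF and repeat/assignment TSV readers/writers, strict validation |
| `c9hap.haplotype_groups` | Four-group haplotype classification, LD (D′/r²), person-level co-carriage |
| `c9hap.repeat_phasing` | PMF training and Bayesian repeat-length-to-haplotype assignment |
| `c9hap.cohort_stats` | Enrichment (chi-square/Fisher), Kruskal–Wallis, Mann–Whitney reports |
| `c9hap.association` | Firth-fallback logistic regression, allelic OR, variant filters, λ, fixed-effects meta |
| `c9hap.synthetic_cohort` | Seeded cohort generator with truth tables for parameter-recovery tests |
| `c9hap.cli` | `c9hap` command-line interface |

## CLI

All commands write results plus a `manifest.json` (seed, config hash,
version) under `--out`. Exit codes: 0 ok, 1 runtime failure, 2 usage.

```sh
# generate a synthetic cohort (VCF + repeat TSV + truth TSV)
c9hap simulate --n 1200 --seed 7 --out run/sim
# or a case/control cohort with allele-frequency enrichment
c9hap simulate --n-cases 400 --n-controls 4200 --seed 7 --out run/cc

# haplotype group counts from a phased VCF
c9hap classify --vcf run/sim/cohort.vcf --out run/classify

# Bayesian repeat-length assignment + group summary
c9hap phase --vcf run/sim/cohort.vcf --repeats run/sim/repeats.tsv \
    --posterior-threshold 0.8 --length-gap 3 --out run/phase

# group statistics from the assignment table
c9hap stats --assignments run/phase/assignments.tsv --out run/stats

# per-variant Firth-fallback association
c9hap assoc --vcf run/cc/cohort.vcf --pheno run/cc/phenotypes.tsv --out run/assoc

# fixed-effects meta-analysis of a studies TSV (columns: study, beta, se)
c9hap meta --studies studies.tsv --out run/meta
```

## Notes

- Repeat lengths are counted in repeat units; `EXP` marks an expanded
  allele (length unknown, above the 30-unit pathological threshold).
- Haplotype extraction requires phased genotypes (`|` GT separator);
  unphased samples are excluded and reported, never imputed.
- The Bayesian classifier accepts a configuration when its posterior is
  ≥ 0.8 or the two measured lengths differ by ≤ 3 units; both thresholds
  are configurable (`PhasingConfig`).
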