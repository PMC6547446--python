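# rrsqc

Caller-agnostic SNP quality control and population-genetic analyses for
reduced-representation sequencing (RRS/RADseq/DArTseq) data at the VCF level.

`rrsqc` ingests multi-sample VCFs from any short-variant caller (Stacks,
SAMtools/bcftools, GATK, ...) into a compact genotype matrix and provides:

- **QC filters**, each a pure, composable operation with a full audit trail:
  minimum mean allelic depth (both alleles), allelic coverage difference,
  technical-replicate reproducibility, putative sex-linkage (XY or ZW),
  maximum observed heterozygosity, call rate, minor allele frequency, and
  one-SNP-per-locus thinning.
- **Replicate QC**: per-locus reproducibility, pooled genotype-call error
  rate (pre/post filtering), and replicate deduplication (keep least
  missing).
- **Diversity statistics**: per-locus H_O/H_E, per-sample multilocus
  heterozygosity, genotype-ratio profiles, dataset summary tables.
- **Cross-callset concordance**: shared-locus Venn partitioning by genomic
  position (with REF/ALT polarity reconciliation) and genotype concordance
  with three discordance classes (hom→hom, hom→het, het→hom).
- **Population structure**: PCoA on squared Euclidean genotype distances and
  pairwise Weir–Cockerham F_ST with percentile bootstrap confidence
  intervals.
- **A synthetic-data generator** (Balding–Nichols populations at a target
  F_ST, HWE genotypes, Poisson allelic depths, technical replicates with a
  controlled discordance rate, planted QC-failure classes) so the entire
  pipeline is testable without any external data.

## Test

```sh
python -m pytest -q tests/
```

## CLI

A single entry point with one subcommand per analysis. All thresholds
default to a standard RRS protocol (70% call rate, MAF 0.01, max observed
het 0.70, 2.5× allelic depth, ≤80% coverage difference, >85% reproducibility,
2000 bootstraps).

```sh
# generate a synthetic dataset (VCF + sample sheet + truth ledger)
rrsqc simulate --seed 1 --out-dir sim/ --n-loci 1000 --samples-per-pop 50,50 \
    --fst 0.10 --missing-rate 0.1 --replicate-pairs 10 --flip-prob 0.05

# run the filter chain (stages lacking prerequisites are skipped by default)
rrsqc filter sim/sim.vcf --sheet sim/sim.samples.tsv --out-dir filtered/

# diversity summary, concordance, PCoA, FST
rrsqc stats filtered/filtered.vcf --sheet sim/sim.samples.tsv --out-dir stats/
rrsqc concordance a.vcf b.vcf c.vcf --out-dir conc/
rrsqc pcoa filtered/filtered.vcf --sheet sim/sim.samples.tsv --out-dir pcoa/
rrsqc fst filtered/filtered.vcf --sheet sim/sim.samples.tsv --out-dir fst/ \
    --boot 2000 --seed 1
```

Every subcommand writes machine-readable outputs (TSV + JSON) and a
`manifest.json` with inputs, resolved configuration, seeds, version and
timings. Logs go to stderr.

The sample sheet is headered delimited text with columns
`sample, population, sex, replicate_group` (sex in
`female`/`male`/`unknown`; samples sharing a `replicate_group` are technical
replicates of one individual).

## Library use

```python
from rrsqc import read_vcf, SampleSheet, FilterConfig, run_filter_chain
from rrsqc.popstructure import pairwise_fst

matrix = read_vcf("calls.vcf")
sheet = SampleSheet.read("samples.tsv")
filtered, report = run_filter_chain(matrix, sheet, FilterConfig(), skip_unmet=True)
print(report.to_dataframe())
for r in pairwise_fst(filtered, sheet, n_boot=2000, seed=1):
    print(r.pop_a, r.pop_b, r.estimate, (r.ci_lower, r.ci_upper))
```
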