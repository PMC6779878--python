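# rhucscreen

Recessive-model exome variant filtering and two-founder-variant panel
screening for renal hypouricemia (RHUC) cohorts, with cohort-level
diagnostic-yield and prevalence statistics, ortholog-conservation profiling,
and a synthetic cohort simulator for end-to-end validation.

## What it does

* **`variant_model`** — domain types (annotated alternate alleles,
  per-individual genotype records) plus readers/writers for a multi-sample
  VCF 4.2 + tab-separated phenotype table representation. Round-trip safe,
  multi-allelic sites split per alternate allele.
* **`hypouricemia_select`** — extreme-hypouricemia case ascertainment
  (serum uric acid strictly below 1.3 mg/dL, secondary-cause exclusion
  flags) and exact prevalence with 3-decimal percent formatting.
* **`recessive_filter`** — the four-step cascade: population-frequency
  filter (MAF > 1% in any populated source removed; absent evidence is not
  rarity), in-house hom/hemizygous control filter, consequence-class
  filter, and bi-allelic collection (homozygous / compound heterozygous /
  hemizygous male; single heterozygotes excluded). Compound-het calls from
  unphased data carry `phase_resolved=False`.
* **`founder_screen`** — two-variant founder-panel classification
  (*SLC22A12* p.Trp258* and p.Arg90His), per-category distribution tables,
  and two deliberately distinct yields: the permissive *screening* yield
  (any panel allele, single hets included) and the strict *bi-allelic
  diagnosis* yield.
* **`conservation_report`** — ortholog residue-conservation profiling for
  candidate missense variants, aggregation of external predictor verdicts
  (never executed, only tabulated), and the combined evidence report.
* **`synthetic_cohort`** — a Hardy–Weinberg cohort simulator with
  class-conditional serum urate, transient (non-genetic) hypouricemia
  mimics, benign decoy variants, and a truth table for recovery scoring;
  plus deterministic reconstruction of the two published cohorts
  (31 discovery / 50 replication subjects) from their genotype
  distributions.

## CLI

```bash
# end-to-end on the bundled reference cohort: select -> filter -> screen -> report
rhucscreen run --demo discovery --out-dir out/

# synthetic cohort (VCF + phenotypes + truth table), fully seeded
rhucscreen simulate --n 10000 --seed 7 --out-dir sim/

# individual stages
rhucscreen select --vcf sim/cohort.vcf --pheno sim/phenotypes.tsv \
    --ua-threshold 1.3 --out cases.txt
rhucscreen filter --vcf sim/cohort.vcf --pheno sim/phenotypes.tsv \
    --maf 0.01 --out diagnoses.jsonl --counts-out counts.json
rhucscreen screen --vcf sim/cohort.vcf --pheno sim/phenotypes.tsv \
    --mode wes --out summary.tsv
rhucscreen conserve --out conservation.tsv
```

Exit codes: 0 ok, 1 stage failure, 2 config error. Outputs carry a
provenance header (version, config hash, seed); reruns with the same config
are byte-identical.

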