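# rbomics

Integrative multi-omics building blocks for retinoblastoma-style tumor
cohorts. The package reimplements, as a tested library, the desk-side
analysis layer that sits downstream of standard callers and aligners:

* **Somatic variant filtering** (`rbomics.variants`) — a deterministic
  post-caller cascade for matched and tumor-only exomes: panel-of-normals
  (fail at ≥ 2 carrying normals), read support (tumor alt reads < 3, or < 8
  with > 1 blood alt read), tumor variant allele fraction < 5%, population
  MAF ≥ 1% in either reference panel, dbSNP membership with rare/unique-
  mapping/clinically-tagged exceptions, and a cohort-wide shared-indel
  germline heuristic.
* **Deleteriousness consensus** (`rbomics.consensus`) — the class-dependent
  two-of-three vote over PolyPhen-2, FATHMM and MetaLR, with exonic indels
  and splicing variants forced deleterious.
* **Arm-level CNV calling** (`rbomics.cnv`) — length-weighted mean log2
  copy-ratio arm scores called gain/loss at > |0.1|; cohort recurrence by a
  within-sample arm-label permutation test (significant at z ≥ 6,
  BH FDR < 0.05); focal amplification flags at z ≥ 3; B-allele-frequency
  based copy-neutral LOH (isodisomy) flags.
* **Peak integration** (`rbomics.peaks`) — high-confidence intersection of
  ChIP-seq replicate peak sets, nearest-TSS peak-to-gene assignment with
  signed strand-aware distances, promoter ±3 kb / 3–10 kb / 10–100 kb /
  >100 kb binning, genomic-feature annotation, differential-expression
  integration and super-enhancer overlap counting.
* **Motif analysis** (`rbomics.motifs`) — IUPAC-consensus and PWM scanning,
  per-region presence matrices, UpSet-style exact co-occurrence counts and
  hypergeometric enrichment with BH adjustment.
* **Single-cell QC** (`rbomics.scqc`) — keep cells with UMIs > 400, 100 to
  6000 genes inclusive and mitochondrial content < 10%; per-group detection
  and log1p-CPM summaries; Fisher-exact gene co-detection.
* **Reporting** (`rbomics.report`) — exact round-half-up percentages and
  oncoprint gene × sample matrix export.
* **Synthetic data** (`rbomics.simulate`) — generators for every input
  above with ground-truth labels (variant truth classes, planted arm
  events, planted peak distances and bins, planted QC failures), so the
  whole pipeline is testable without controlled-access data.

## Worked example

```python
from rbomics.simulate import CohortSimConfig, simulate_variant_cohort
from rbomics.variants import run_cascade
from rbomics.consensus import classify_table

cfg = CohortSimConfig(n_tumors=20, somatic_rate=12, germline_rate=25,
                      artifact_rate=8, frac_matched=0.8, seed=7)
table, pon = simulate_variant_cohort(cfg)
decisions, kept = run_cascade(table, pon)
print(f"cohort: {len(table)} called variants in {cfg.n_tumors} tumors, "
      f"panel of {len(pon)} recurrent normal keys")
print(f"kept {len(kept)} variants "
      f"({(kept['truth_class'] == 'somatic').sum()} somatic, "
      f"{(kept['truth_class'] == 'germline').sum()} germline, "
      f"{(kept['truth_class'] == 'artifact').sum()} artifact)")
classified = classify_table(kept)
print(f"deleterious: {int(classified['deleterious'].sum())} "
      f"of {len(classified)} kept variants")
```

prints

```
cohort: 908 called variants in 20 tumors, panel of 396 recurrent normal keys
kept 413 variants (277 somatic, 119 germline, 17 artifact)
deleterious: 257 of 413 kept variants
```

The cascade keeps almost all planted somatic calls while discarding most
artifacts (low allele fraction / read support) and the germline variants
that are visible to it (panel of normals, population frequency, dbSNP,
shared indels); rare private germline variants in unmatched tumors are not
removable by any of these rules, which is exactly the tumor-only calling
gap the matched-blood read-support rule addresses. The consensus step then
labels each kept variant by the two-of-three predictor vote or by the
indel/splicing override.

The same stages are available from the command line:

```sh
rbomics simulate --preset cohort --seed 7 --out sim/
rbomics filter-variants --variants sim/variants.tsv --pon sim/pon.tsv --out out/
rbomics cnv-arms --segments segments.tsv --n-perm 10000 --seed 1 --out out/
rbomics integrate-peaks --peaks a.bed b.bed --genes genes.tsv --de de.tsv --out out/
rbomics sc-qc --matrix mtxdir/ --out out/
```

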