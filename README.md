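# amplistr

Forensic amplicon STR/SNP typing, stutter-aware genotype calling, and
evaluation study designs for massively parallel sequencing (MPS) panels.

Forensic laboratories moving from capillary electrophoresis (CE) to MPS
type large multiplexes — here 58 short tandem repeats (27 autosomal, 7
X, 24 Y) and 94 human-identification SNPs plus ancestry/phenotype
markers — from amplicon reads. `amplistr` provides the computational
pieces of that workflow as a reusable, tested library:

- **Flank-anchored typing** — reads are sorted to loci by locating both
  flanking sequences within a per-locus mismatch budget (substitutions
  count singly, a contiguous indel counts once), the repeat region is
  decomposed into ordered motif blocks, and flanking variants are
  reported with GRCh37 coordinates.
- **Sequence-based nomenclature** — bracketed block notation (e.g.
  `[AGAT]12 [AGAC]9`) plus the length-based CE designation
  `CE = (units × motif_len + partial bases + net flanking indel) /
  motif_len`, so an `[AAAGA]5` Penta D allele with a 13 bp upstream
  deletion is named CE 2.2 with `del:45056073-45056085` on record.
- **Threshold/alert calling** — depth-dependent interpretation (IT) and
  analytical (AT) thresholds (30/10 reads below 650 locus reads,
  4.5%/1.5% of the locus total above), structural stutter filters at
  per-locus fixed fractions of the parent allele, imbalance /
  allele-count / low-depth / AT-zone alerts, and a single-source
  indicator that fails a sample when autosomal-STR violations exceed 6
  or HID-SNP imbalance violations exceed 11.
- **SNP calling by direct allele counting** — Q30 3′ trimming, a 20-read
  allele minimum, heterozygote balance in A,C,G,T order, and noise as
  the off-genotype read fraction.
- **QC statistics** — per-locus depth distributions with 1.5×IQR
  outliers, heterozygote balance, stutter ratios with same-length A/B/C
  ranking, stutter-vs-repeat-number regression, SNP noise exceedance.
- **Study runners + read simulator** — duplicate reproducibility, CE
  concordance, dilution sensitivity (1000 → 7.8 pg) and two-person
  mixture series (1000:1 → 1:1000), exercised end-to-end on a synthetic
  amplicon-read generator with Poisson template sampling, log-normal
  depth and imbalance, linear-in-repeat-length stutter, PCR ratio
  compression and per-base errors.

## Worked example

Simulate a male single-source sample, type it, and call the profile
(`--depth-scale 0.2` shrinks per-locus depths for a quick demo):

```sh
amplistr simulate --seed 7 --sex M --depth-scale 0.2 --out demo/sim
amplistr type demo/sim/sample.fastq --sample demo --out demo/typed
amplistr call demo/sim/sample.fastq --sample demo --sex M --out demo/called
```

The typing step reports `52063 reads assigned, 0 unassigned` and writes
an allele table; for the compound locus D12S391 it contains:

```text
sample  locus    ce  bracketed          flank_variants  reads  fraction
demo    D12S391  18  [AGAT]11 [AGAC]7   .               269    0.4210
demo    D12S391  20  [AGAT]11 [AGAC]9   .               232    0.3631
demo    D12S391  17  [AGAT]10 [AGAC]7   .               26     0.0407
demo    D12S391  19  [AGAT]10 [AGAC]9   .               19     0.0297
```

The two deep sequences are the heterozygote's alleles (CE 18 and 20);
the two shallow ones are their n−1 stutters, one repeat unit shorter in
the `[AGAT]` block, at 9.7% and 8.2% of their parents — the caller
filters them structurally rather than reporting them as alleles. The
interpreted profile (`demo/called/indicator.txt`) reads:

```text
single_source   pass
str_violations  0.0
snp_violations  0.0
```

i.e. no imbalance or allele-count violations, so the sample is
classified single-source. Study designs run the full pipeline, e.g.

```sh
amplistr study mixtures --seed 3 --out demo/mix      # 15 ratios, duplicates
amplistr study sensitivity --seed 3 --out demo/sens  # 8 dilution levels
```

Library use mirrors the CLI: `default_panel()`, `random_truth_profile`,
`simulate_reads`, `assign_reads_to_loci`, `report_sequence_alleles`,
`call_sample`, and the `run_*` study functions; see `docs/methods.md`
for the models and parameter choices.

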