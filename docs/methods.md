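# Methods

`amplistr` implements the computational core of a forensic
massively-parallel-sequencing (MPS) typing workflow for a combined
STR/SNP amplicon panel: read sorting by flanking sequences, sequence-based
allele nomenclature, threshold- and alert-based genotype calling with a
mixture indicator, QC statistics, and the four evaluation study designs
(duplicate reproducibility, CE concordance, dilution sensitivity, mixture
series) driven by a synthetic read generator. This note records the
models, the parameters that matter, and the numerical choices.

## Panel model

A panel couples marker definitions with interpretation parameters
(`ThresholdSet`). STR loci carry GRCh37 coordinates of the analysed
repeat range, upstream/downstream flanking sequences, and an ordered list
of motif blocks. Each block has a role in length-based (CE) naming:
`unit` blocks contribute whole repeat units, `partial` blocks contribute
their bases to the fractional part (a trailing `[AG]` yields a `.2`
allele), and `none` blocks are fixed intervening sequence ignored by the
CE count (the `[TA]`/`[TCA]`/`[TCCATA]` spacers of D21S11, the 7-base
`GAAAGGA` spacer of DXS10135). Counting motifs are 1–6 bases; intervening
blocks may be longer.

The bundled default panel has 27 autosomal, 7 X and 24 Y STRs plus 94
human-identification (HID), 56 ancestry (AIM) and 24 phenotype SNPs. The
eight loci with publicly printed repeat structures (D21S11, D12S391,
D1S1656, D19S433, D2S1338, D18S51, Penta D, DXS10135) are encoded from
those structures; all other flanks, structures and coordinates are
clearly-synthetic placeholders generated deterministically from the locus
name. Generic allele ranges are sized so that the expected n−1 stutter
ratio at a locus's longest allele is about 0.6× its stutter-filter
threshold — in the real chemistry the vendor's per-locus filters sit
above the observed stutter, and the panel reproduces that relationship.
Four loci (D1S1656, D19S433, HPRTB, DYS522) ship an elevated flank
mismatch budget of 5 (default 3), reflecting error-prone flanks.

## Typing

**Assignment.** A read is assigned to a locus iff both flanks are found,
each within the locus's mismatch budget. The budget counts substitutions
individually and each contiguous indel run as a single event, so a 13 bp
flanking deletion costs one event, not thirteen. Candidate loci are
identified from the intact outer 12 bp anchor of either flank; a
widened-distance search (for indel-bearing flanks) runs only for
anchor-identified candidates, and exact ties between loci are left
unassigned.

**Boundary refinement.** An indel that abuts the repeat region is
ambiguous at the edit-distance level (deleting flank bases or repeat
bases can cost the same). The flank/repeat boundary is therefore refined
by requiring the inner sequence to decompose into whole motif blocks,
scanning boundaries in maximal-repeat-span order — the convention that
the repeat region is maximal and indels belong to the flank. This is what
lets a `[AAAGA]5` allele with a 13 bp upstream deletion type as CE 2.2
with the deletion reported at its genomic span.

**Parsing.** Repeat regions are decomposed greedily left-to-right with
backtracking over the ordered blocks; ties prefer larger counts in
earlier blocks, matching the bracketed convention for compound repeats.
Unparseable reads are tallied per locus and stay in the denominator of
the reporting rule. Only sequences with reads strictly above 1% of the
locus total are reported ("above" read literally).

**Flank variants.** Observed flanks are aligned to the reference flank
(global alignment); the edit transcript is emitted as
substitution/deletion/insertion records with 1-based GRCh37 coordinates.
Equal-cost placements resolve leftmost; deletions that could shift within
a repeated context are flagged ambiguous. Net flanking indel length feeds
the CE designation: `CE = (units × motif_len + partial bases + net
indel) / motif_len`, remainder appended after a dot.

**SNPs.** Instead of genome mapping plus a variant caller, SNP alleles
are counted directly at the offset of flank-anchored reads; the numeric
rules of the evaluated workflow are kept: Q30 3′ quality trimming,
alleles below 20 reads discarded, heterozygote balance (Hb) as earlier
base over later base in A,C,G,T order, and noise as the fraction of reads
off the called genotype. More than two surviving bases is flagged as a
possible mixture with the top two retained.

## Calling and alerts

Interpretation (IT) and analytical (AT) thresholds are depth-dependent:
below 650 locus reads, 30 and 10 reads; at or above, user-defined
fractions of the locus total (defaults 4.5% and 1.5%), rounded up. A
sequence is called iff its reads are strictly above IT; sequences in
[AT, IT] are flagged for the analyst (at-zone alert).

Stutter filtering is structural + ratio-based: a sequence is removed only
if it is an exact n−1/n−2/n+1 block-count derivative of a deeper retained
sequence *and* its reads are at or below the locus's threshold fraction
of that parent (n−2/n+1 thresholds default to half the n−1 threshold). A
sequence at a stutter position that exceeds the threshold is retained and
typically raises an allele-count alert — the behaviour observed at
low-threshold loci. With several consistent parents the deepest is used
and the observation flagged.

Alerts: `imbalance` when Hb (longest/shortest allele reads for STRs;
isometric heterozygotes tie-break by CE then bracketed name and are
flagged) leaves the common band (0.5, 2.0); `allele_count` when retained
alleles exceed the expected ploidy (2 autosomal / X-female, 1 X-male, 1
per amplicon for Y); `low_read_depth` when the locus total is below 2×
the absolute IT (60 reads) or nothing clears IT.

**Single-source indicator.** STR violations sum imbalance and
allele-count alerts over the autosomal STRs; SNP violations count
imbalance alerts over the HID SNPs (AIM/phenotype SNPs excluded). The
sample passes iff STR violations ≤ 6 AND SNP violations ≤ 11. The limits
are inclusive: that is the only reading that maps all sixteen published
mixture-series alert rows to their printed verdicts (the 100:1 row sums
to exactly 6 and passes).

## Synthetic read generator

Per locus and sample:

1. **Templates.** Copies per distinct allele ~ Poisson(input_pg / 3.3 pg
   × dose); in mixtures, contributors' templates of identical alleles
   pool before amplification. Zero copies is an irreversible drop-out.
2. **Depth.** The locus read total is log-normal (σ = 0.35) around the
   locus mean (defaults from the bundled depth table; medians 52–18 164
   reads for STRs, ~505 for SNPs), scaled by a saturation factor
   input/(input + 80 pg) normalised to 1 at 1 ng. This reproduces the
   loss of yield below ~250 pg without affecting full-input runs.
3. **Allele shares.** Reads are split proportionally to copies^γ × a
   per-allele log-normal imbalance factor (σ = 0.22). γ = 0.6 models the
   ratio compression of late-cycle multiplex PCR: minor mixture
   contributors are over-represented in reads relative to template, which
   is what makes ~1:25–1:100 mixtures detectable at all.
4. **Stutter.** Every counting block of length L ≥ 4 units emits an n−1
   stutter at rate slope × (L − 4), clipped at 0.5, with motif-length
   slopes 3%/unit (tri), 1.2% (tetra), 0.5% (penta), 0 (hexa); n−2 and
   n+1 stutters at 8% and 4% of the n−1 rate. Interrupting blocks reset
   the uninterrupted count because blocks slip independently — compound
   repeats therefore produce several distinct same-length stutters.
5. **Errors.** Each emitted read acquires a single-base substitution with
   probability 1 − (1 − e)^length (e = 0.001/base), written at Q15 in
   FASTQ output (all other bases Q37) so that Q30 trimming is
   exercisable.

`SimulationParams.noise_free()` gives the deterministic-depth, error- and
stutter-free limit used for exactness checks. All randomness flows
through one explicit `numpy` Generator; equal seeds give byte-identical
FASTQ output.

**What the generator does not emulate.** Flow-cell effects, paired-end
structure, adapter read-through, PCR chimeras, locus-specific
amplification efficiency beyond the configured means, sequence-context
error hot-spots, and degraded-DNA fragment-length effects. Passing the
study suites therefore shows that the *analysis rules* behave as
described under a faithful statistical emulation — not that the generator
predicts any particular instrument's error profile.

## Study designs and problem sizes

The study runners execute simulate → type → call end-to-end.
Reproducibility compares duplicate libraries locus by locus (loci
uncalled in both replicates leave the denominator; a supernumerary allele
in one replicate is a drop-in, annotated "consistent with stutter" when
it is an n−1 derivative of a shared allele). CE concordance collapses
sequence alleles to CE labels, so flanking-indel alleles match the
fragment-length name by construction. The sensitivity suite runs the
eight dilution levels 1000…7.8 pg at 50 replicates per level; the mixture
suite runs the fifteen ratios 1000:1…1:1000 in duplicate. These replicate
counts keep the full test suite in the low tens of seconds on one CPU
while leaving the monotonicity and verdict assertions far from their
noise floors.

## Known limitations

- The single-source crossover in simulation sits at 1:100 rather than the
  1:50–1:100 band seen on the real instrument; with the absolute 20-read
  SNP allele rule a ~1% template minor (≈3% of reads after PCR
  compression) remains callable at typical SNP depths. The verdict
  pattern (balanced fail, extreme pass) and the Y-STR side channel are
  reproduced.
- Dual-amplicon Y loci (DYS385a/b, DYF387S1) share one flank definition
  for both amplicons.
- Isometric heterozygote Hb orientation is a convention; the length-based
  formula does not define it.
- Amelogenin sex typing is out of scope; sample sex is taken from the
  truth manifest or inferred from Y-locus read presence.
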