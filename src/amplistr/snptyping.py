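"""SNP typing from flank-anchored allele counts.

Replaces a mapping + variant-caller stage with direct base counting at the
SNP offset of flank-anchored reads, while keeping the numeric calling
rules of the evaluated workflow: Q30 3'-end quality trimming, a 20-read
minimum per allele, heterozygote balance in A,C,G,T order, and noise as
the fraction of reads differing from the called genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel import SnpLocusDef, ThresholdSet
from .strtyping import LocusReadGroup

__all__ = ["SnpObservation", "SnpGenotype", "quality_trim",
           "count_snp_alleles", "call_snp_genotype", "snp_hb", "snp_noise"]

_BASES = "ACGT"


def quality_trim(sequence: str, quality: str, min_q: int = 30,
                 offset: int = 33) -> tuple[str, str]:
    """Trim low-quality bases from the 3' end of a read.

    Bases are removed from the end while their Phred score is below
    ``min_q``.  The result may be empty; such reads are excluded
    downstream.
    """
    if len(sequence) != len(quality):
        raise ValueError("malformed record: sequence and quality lengths differ")
    end = len(sequence)
    while end > 0 and ord(quality[end - 1]) - offset < min_q:
        end -= 1
    return sequence[:end], quality[:end]


@dataclass
class SnpObservation:
    """Per-base read tallies at one SNP locus."""

    locus: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(_BASES, 0))
    discarded_low_reads: dict[str, int] = field(default_factory=dict)
    excluded_reads: int = 0  # indel-disrupted offset

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def count_snp_alleles(group: LocusReadGroup, locus: SnpLocusDef) -> SnpObservation:
    """Tally the base at the SNP offset for every read assigned to a locus.

    Reads whose inner segment is not a single base (an indel disrupting
    the offset) are excluded from the tallies.
    """
    obs = SnpObservation(locus.name)
    for read, (count, split) in group.sequences.items():
        inner = read[split.i:split.j]
        if len(inner) == 1 and inner in _BASES:
            obs.counts[inner] += count
        else:
            obs.excluded_reads += count
    return obs


@dataclass
class SnpGenotype:
    locus: str
    alleles: tuple[str, ...]  # 0, 1 or 2 bases, alphabetical
    hb: float | None
    noise: float | None
    total_reads: int
    extra_alleles: tuple[str, ...] = ()  # >2 surviving bases: mixture flag

    @property
    def called(self) -> bool:
        return bool(self.alleles)

    @property
    def heterozygous(self) -> bool:
        return len(self.alleles) == 2


def call_snp_genotype(obs: SnpObservation, thresholds: ThresholdSet) -> SnpGenotype:
    """Hard-threshold genotype call: bases with at least
    ``snp_min_allele_reads`` reads survive; two survivors make a
    heterozygote, one a homozygote, none a locus drop-out.  More than two
    survivors are flagged as a possible mixture and the top two retained.
    """
    surviving = [b for b in _BASES if obs.counts[b] >= thresholds.snp_min_allele_reads]
    obs.discarded_low_reads = {b: obs.counts[b] for b in _BASES
                               if 0 < obs.counts[b] < thresholds.snp_min_allele_reads}
    extra: tuple[str, ...] = ()
    if len(surviving) > 2:
        ranked = sorted(surviving, key=lambda b: (-obs.counts[b], b))
        extra = tuple(sorted(ranked))
        surviving = sorted(ranked[:2])
    alleles = tuple(sorted(surviving))
    geno = SnpGenotype(obs.locus, alleles, None, None, obs.total_reads,
                       extra_alleles=extra)
    geno.hb = snp_hb(obs, geno)
    geno.noise = snp_noise(obs, geno)
    return geno


def snp_hb(obs: SnpObservation, genotype: SnpGenotype) -> float | None:
    """Heterozygote balance: reads of the alphabetically earlier base
    divided by reads of the later base (A, C, G, T order)."""
    if not genotype.heterozygous:
        return None
    first, second = genotype.alleles
    if obs.counts[second] == 0:
        return float("inf")
    return obs.counts[first] / obs.counts[second]


def snp_noise(obs: SnpObservation, genotype: SnpGenotype) -> float | None:
    """Noise: fraction of reads differing from the called genotype."""
    if not genotype.called or obs.total_reads == 0:
        return None
    genotype_reads = sum(obs.counts[b] for b in set(genotype.alleles))
    return (obs.total_reads - genotype_reads) / obs.total_reads
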