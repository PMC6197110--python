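"""Synthetic amplicon-read generator with ground-truth manifests.

The generator emulates the statistical structure of forensic multiplex
amplicon sequencing: per-locus depth variation (log-normal around
configurable locus means), heterozygote imbalance, sequence-dependent PCR
stutter that grows linearly with the length of the uninterrupted repeat,
per-base call errors, template-limited drop-out at low DNA input, and
two-person mixtures with PCR ratio compression.

Model sketch, per locus and sample:

* template copies per distinct allele ~ Poisson(input_pg / pg_per_copy x
  dose); zero copies means the allele cannot appear (drop-out);
* the locus read total is log-normal around the locus mean, scaled by a
  saturation factor input/(input + K) that mimics the loss of sequencing
  yield below ~250 pg input;
* reads are shared among alleles proportionally to copies**gamma times a
  per-allele log-normal imbalance factor; gamma < 1 models the ratio
  compression of late-cycle multiplex PCR (minor mixture contributors are
  over-represented in reads relative to template);
* each repeat block of length L above the stutter floor emits an n-1
  stutter at rate slope x (L - floor), with n-2 and n+1 stutters at fixed
  fractions of that rate; interrupting blocks reset the uninterrupted
  count because blocks slip independently;
* each emitted read acquires a single-base substitution with probability
  1 - (1 - e)**len, written at Q15 in FASTQ output (all other bases Q37).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .panel import PanelConfig, StrLocusDef, default_depth_means
from .strtyping import bracketed_name, build_inner_sequence, ce_allele_number

__all__ = [
    "TruthAllele", "TruthProfile", "SimulationParams", "SampleSim",
    "build_allele_sequence", "generate_stutters", "draw_locus_reads",
    "simulate_reads", "simulate_sample", "simulate_mixture",
    "random_truth_profile",
]

_QUAL_OK = "F"   # Phred+33 Q37
_QUAL_ERR = "0"  # Phred+33 Q15


@dataclass(frozen=True)
class TruthAllele:
    """Ground-truth sequence allele: block counts plus flank variants.

    ``flank_variants`` entries are (kind, side, offset, payload) with the
    0-based ``offset`` into the flank: ``("deletion", "upstream", 7, 13)``
    deletes 13 bases starting at flank position 7, ``("substitution",
    "downstream", 5, "T")`` substitutes one base, ``("insertion",
    "upstream", 5, "ACG")`` inserts after position 5.
    """

    counts: tuple[int, ...]
    flank_variants: tuple[tuple, ...] = ()

    def name(self, locus: StrLocusDef) -> str:
        net = 0
        for kind, _side, _off, payload in self.flank_variants:
            if kind == "deletion":
                net -= int(payload)
            elif kind == "insertion":
                net += len(payload)
        ce = ce_allele_number(locus.structure, self.counts,
                              locus.canonical_motif_len, net)
        label = f"{locus.name}[CE{ce}] {bracketed_name(locus.structure, self.counts)}"
        if self.flank_variants:
            label += " " + ";".join(f"{k}@{s}:{o}" for k, s, o, _p in
                                    self.flank_variants)
        return label


@dataclass
class TruthProfile:
    """Ground-truth genotypes for one donor."""

    sample_id: str
    sex: str  # "M" | "F"
    str_alleles: dict[str, tuple[TruthAllele, ...]]
    snp_genotypes: dict[str, tuple[str, str]]

    def validate(self, panel: PanelConfig) -> None:
        for locus in panel.str_loci:
            alleles = self.str_alleles.get(locus.name, ())
            expected = locus.expected_allele_count(self.sex)
            if locus.ploidy_class == "Y" and self.sex == "F" and alleles:
                raise ValueError(f"{self.sample_id}: female profile has Y alleles "
                                 f"at {locus.name}")
            if expected and not 1 <= len(alleles) <= max(2, expected):
                raise ValueError(f"{self.sample_id}: {locus.name} has "
                                 f"{len(alleles)} alleles, expected ~{expected}")


@dataclass
class SimulationParams:
    """Generative parameters; defaults emulate a 1 ng single-source library."""

    depth_means: dict[str, float] = field(default_factory=default_depth_means)
    depth_log_sd: float = 0.35
    hb_log_sd: float = 0.22
    stutter_slope_by_motif_len: dict[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 0.0, 3: 0.03, 4: 0.012,
                                 5: 0.005, 6: 0.0})
    stutter_floor_repeats: int = 4
    n2_fraction: float = 0.08
    np1_fraction: float = 0.04
    base_error_rate: float = 0.001
    pg_per_haploid_copy: float = 3.3
    input_pg: float = 1000.0
    reference_input_pg: float = 1000.0
    depth_half_saturation_pg: float = 80.0
    pcr_compression: float = 0.6  # gamma; 1.0 = no ratio compression
    depth_scale: float = 1.0  # global multiplier for problem-size control

    def __post_init__(self) -> None:
        for rate in (self.base_error_rate, self.n2_fraction, self.np1_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.pg_per_haploid_copy <= 0 or self.input_pg < 0:
            raise ValueError("template amounts must be positive")

    def noise_free(self) -> "SimulationParams":
        """Deterministic-depth, error-free, stutter-free limit."""
        return replace(
            self, depth_log_sd=0.0, hb_log_sd=0.0, base_error_rate=0.0,
            stutter_slope_by_motif_len={k: 0.0 for k in
                                        self.stutter_slope_by_motif_len},
            pcr_compression=1.0)

    def mean_depth(self, locus_name: str) -> float:
        return self.depth_means.get(locus_name, 1000.0) * self.depth_scale

    def saturation(self, input_pg: float) -> float:
        k = self.depth_half_saturation_pg
        if k <= 0:
            return 1.0
        ref = self.reference_input_pg / (self.reference_input_pg + k)
        return (input_pg / (input_pg + k)) / ref


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _apply_flank_variants(up: str, down: str, variants) -> tuple[str, str]:
    ups = [(o, k, p) for k, s, o, p in variants if s == "upstream"]
    downs = [(o, k, p) for k, s, o, p in variants if s == "downstream"]
    for flank_len, items in ((len(up), ups), (len(down), downs)):
        for off, kind, payload in items:
            span = int(payload) if kind == "deletion" else 1
            if not 0 <= off <= flank_len - (span if kind != "insertion" else 0):
                raise ValueError(
                    f"flank variant at offset {off} outside the analysed range")

    def apply(flank: str, items) -> str:
        for off, kind, payload in sorted(items, reverse=True):
            if kind == "deletion":
                flank = flank[:off] + flank[off + int(payload):]
            elif kind == "substitution":
                flank = flank[:off] + payload + flank[off + 1:]
            elif kind == "insertion":
                flank = flank[:off + 1] + payload + flank[off + 1:]
            else:
                raise ValueError(f"unknown flank variant kind {kind!r}")
        return flank

    return apply(up, ups), apply(down, downs)


def build_allele_sequence(locus: StrLocusDef, allele: TruthAllele) -> str:
    """Full amplicon sequence: flanks (with variants applied) + repeats."""
    up, down = _apply_flank_variants(locus.upstream_flank, locus.downstream_flank,
                                     allele.flank_variants)
    return up + build_inner_sequence(locus.structure, allele.counts) + down


# ---------------------------------------------------------------------------
# Stutter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StutterSpec:
    counts: tuple[int, ...]
    relation: str  # "n-1" | "n-2" | "n+1"
    block_index: int
    rate: float


def generate_stutters(counts: tuple[int, ...], locus: StrLocusDef,
                      params: SimulationParams) -> list[StutterSpec]:
    """Slippage products of one parent allele with their expected ratios.

    Any sub-repeat block may slip, so compound repeats can produce several
    distinct same-length stutter sequences.  The n-1 rate for a block of
    L uninterrupted units is slope x (L - floor), clipped to [0, 0.5];
    n-2 and n+1 stutters occur at fixed fractions of the n-1 rate.
    """
    specs: list[StutterSpec] = []
    floor = params.stutter_floor_repeats
    for bi, (block, count) in enumerate(zip(locus.structure, counts)):
        if block.ce_role == "none":
            continue
        slope = params.stutter_slope_by_motif_len.get(len(block.motif), 0.0)
        if slope <= 0.0 or count < floor:
            continue
        rate = min(0.5, slope * (count - floor))
        if rate <= 0.0:
            continue
        specs.append(StutterSpec(counts[:bi] + (count - 1,) + counts[bi + 1:],
                                 "n-1", bi, rate))
        if count >= 2 and params.n2_fraction > 0:
            specs.append(StutterSpec(counts[:bi] + (count - 2,) + counts[bi + 1:],
                                     "n-2", bi, rate * params.n2_fraction))
        if count + 1 <= block.max_count and params.np1_fraction > 0:
            specs.append(StutterSpec(counts[:bi] + (count + 1,) + counts[bi + 1:],
                                     "n+1", bi, rate * params.np1_fraction))
    return specs


# ---------------------------------------------------------------------------
# Per-locus read drawing
# ---------------------------------------------------------------------------

@dataclass
class LocusSim:
    """Emitted reads and bookkeeping for one locus of one sample."""

    locus: str
    reads: list  # (sequence, count, error_position | None)
    allele_reads: dict  # truth allele name -> clean parent reads
    stutter_reads: int
    error_reads: int

    @property
    def total_reads(self) -> int:
        return sum(c for _s, c, _e in self.reads)


def _inject_errors(seq: str, count: int, rate: float,
                   rng: np.random.Generator) -> list[tuple[str, int, int | None]]:
    """Split ``count`` copies of ``seq`` into clean reads and reads with a
    single substitution at a random position (single-error approximation
    of an iid per-base error process)."""
    if rate <= 0.0 or count == 0:
        return [(seq, count, None)]
    p_read = 1.0 - (1.0 - rate) ** len(seq)
    n_err = int(rng.binomial(count, p_read))
    out: list[tuple[str, int, int | None]] = []
    if count - n_err:
        out.append((seq, count - n_err, None))
    if n_err:
        positions = rng.integers(0, len(seq), size=n_err)
        shifts = rng.integers(1, 4, size=n_err)
        bucket: Counter = Counter(zip(positions.tolist(), shifts.tolist()))
        bases = "ACGT"
        for (pos, shift), n in bucket.items():
            orig = bases.index(seq[pos]) if seq[pos] in bases else 0
            alt = bases[(orig + shift) % 4]
            out.append((seq[:pos] + alt + seq[pos + 1:], n, pos))
    return out


def draw_locus_reads(weighted_alleles, locus, params: SimulationParams,
                     rng: np.random.Generator, total_input_pg: float | None = None,
                     nominal_alleles: int | None = None) -> LocusSim:
    """Draw the full read set for one locus.

    ``weighted_alleles`` is a list of ``(TruthAllele | str, template_pg)``
    pairs; template picograms already include allele dose and contributor
    weight.  For SNP loci the allele is the base string.
    """
    is_str = isinstance(locus, StrLocusDef)
    if total_input_pg is None:
        total_input_pg = sum(w for _a, w in weighted_alleles)
    if nominal_alleles is None:
        nominal_alleles = (locus.n_amplicons if getattr(locus, "ploidy_class", "")
                           == "Y" else 2) if is_str else 2
    gamma = params.pcr_compression
    ref_copies = params.reference_input_pg / params.pg_per_haploid_copy / 2.0
    w_ref = nominal_alleles * ref_copies ** gamma

    copies = [int(rng.poisson(pg / params.pg_per_haploid_copy))
              for _a, pg in weighted_alleles]
    weights = []
    for c in copies:
        if c == 0:
            weights.append(0.0)
            continue
        ln = (rng.lognormal(-params.hb_log_sd ** 2 / 2.0, params.hb_log_sd)
              if params.hb_log_sd > 0 else 1.0)
        weights.append((c ** gamma) * ln)
    w_sum = float(sum(weights))

    mean = params.mean_depth(locus.name) * params.saturation(total_input_pg)
    if w_sum <= 0.0 or mean <= 0.0:
        return LocusSim(locus.name, [], {}, 0, 0)
    if params.depth_log_sd > 0:
        locus_total = rng.lognormal(np.log(mean) - params.depth_log_sd ** 2 / 2.0,
                                    params.depth_log_sd)
    else:
        locus_total = mean
    locus_total = int(round(locus_total * min(w_sum / w_ref, 4.0)))
    if locus_total <= 0:
        return LocusSim(locus.name, [], {}, 0, 0)

    shares = np.asarray(weights) / w_sum
    allele_counts = rng.multinomial(locus_total, shares)

    reads: list[tuple[str, int, int | None]] = []
    allele_reads: dict[str, int] = {}
    stutter_total = 0
    error_total = 0
    emitted: list[tuple[str, int, str | None]] = []  # (seq, count, allele key)
    for (allele, _pg), n in zip(weighted_alleles, allele_counts):
        n = int(n)
        if n == 0:
            continue
        if is_str:
            seq = build_allele_sequence(locus, allele)
            key = allele.name(locus)
        else:
            seq = locus.upstream_flank + allele + locus.downstream_flank
            key = allele
        emitted.append((seq, n, key))
        if is_str:
            for spec in generate_stutters(allele.counts, locus, params):
                s = int(rng.binomial(n, spec.rate))
                if s == 0:
                    continue
                emitted.append((build_allele_sequence(
                    locus, TruthAllele(spec.counts, allele.flank_variants)),
                    s, None))
    for seq, n, key in emitted:
        for out_seq, out_n, err_pos in _inject_errors(seq, n,
                                                      params.base_error_rate, rng):
            if err_pos is not None:
                error_total += out_n
            elif key is not None:
                allele_reads[key] = allele_reads.get(key, 0) + out_n
            else:
                stutter_total += out_n
            reads.append((out_seq, out_n, err_pos))
    return LocusSim(locus.name, reads, allele_reads, stutter_total, error_total)


# ---------------------------------------------------------------------------
# Whole-sample simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleSim:
    """In-memory simulated sample: pooled reads plus ground truth."""

    sample_id: str
    sex: str
    loci: dict[str, LocusSim]
    truth: TruthProfile | None = None
    mixture: tuple[TruthProfile, TruthProfile, float] | None = None

    def pooled_reads(self) -> list[tuple[str, int]]:
        """All reads of the sample as (sequence, count), order-stable."""
        pooled: dict[str, int] = {}
        for sim in self.loci.values():
            for seq, n, _e in sim.reads:
                pooled[seq] = pooled.get(seq, 0) + n
        return list(pooled.items())

    @property
    def total_reads(self) -> int:
        return sum(sim.total_reads for sim in self.loci.values())


def _weighted_alleles_for(locus, profiles_weights: list[tuple[TruthProfile, float]],
                          params: SimulationParams):
    """Pool contributor templates: identical alleles merge before PCR."""
    pooled: dict = {}
    order: list = []
    is_str = isinstance(locus, StrLocusDef)
    for profile, pg in profiles_weights:
        if is_str:
            alleles: Iterable = profile.str_alleles.get(locus.name, ())
        else:
            alleles = profile.snp_genotypes.get(locus.name, ())
        if not alleles:
            continue
        per_allele_pg = pg / 2.0  # pg of a haploid dose
        for a in alleles:
            if a not in pooled:
                pooled[a] = 0.0
                order.append(a)
            pooled[a] += per_allele_pg
    return [(a, pooled[a]) for a in order]


def simulate_reads(profiles_weights: list[tuple[TruthProfile, float]],
                   panel: PanelConfig, params: SimulationParams,
                   rng: np.random.Generator, sample_id: str = "sim") -> SampleSim:
    """Simulate one library (single-source or mixture) in memory.

    ``profiles_weights`` lists (truth profile, template pg in the first
    PCR); weights of a mixture should sum to ``params.input_pg``.
    """
    total_pg = sum(pg for _p, pg in profiles_weights)
    loci: dict[str, LocusSim] = {}
    for locus in list(panel.str_loci) + list(panel.snp_loci):
        weighted = _weighted_alleles_for(locus, profiles_weights, params)
        nominal = None
        if isinstance(locus, StrLocusDef) and locus.ploidy_class == "Y":
            nominal = locus.n_amplicons
        loci[locus.name] = draw_locus_reads(weighted, locus, params, rng,
                                            total_input_pg=total_pg,
                                            nominal_alleles=nominal)
    sex = profiles_weights[0][0].sex
    truth = profiles_weights[0][0] if len(profiles_weights) == 1 else None
    mixture = None
    if len(profiles_weights) == 2:
        (a, pga), (b, pgb) = profiles_weights
        mixture = (a, b, pga / pgb if pgb else float("inf"))
    return SampleSim(sample_id, sex, loci, truth=truth, mixture=mixture)


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(sim: SampleSim, path) -> int:
    """Expand a simulated sample to FASTQ (Phred+33); returns read count."""
    serial = 0
    with _open_out(path) as fh:
        for locus_name, locus_sim in sim.loci.items():
            for seq, count, err_pos in locus_sim.reads:
                qual = _QUAL_OK * len(seq)
                if err_pos is not None:
                    qual = qual[:err_pos] + _QUAL_ERR + qual[err_pos + 1:]
                for _ in range(count):
                    serial += 1
                    fh.write(f"@{sim.sample_id}:{serial}\n{seq}\n+\n{qual}\n")
    return serial


def write_manifest(sim: SampleSim, path) -> None:
    """Tab-separated ground-truth manifest for a simulated sample."""
    with open(path, "w") as fh:
        fh.write("sample\tlocus\tallele\tallele_reads\tstutter_reads\t"
                 "error_reads\ttotal_reads\n")
        for name, locus_sim in sim.loci.items():
            if not locus_sim.allele_reads:
                fh.write(f"{sim.sample_id}\t{name}\t.\t0\t"
                         f"{locus_sim.stutter_reads}\t{locus_sim.error_reads}\t"
                         f"{locus_sim.total_reads}\n")
                continue
            for allele_name, n in locus_sim.allele_reads.items():
                fh.write(f"{sim.sample_id}\t{name}\t{allele_name}\t{n}\t"
                         f"{locus_sim.stutter_reads}\t{locus_sim.error_reads}\t"
                         f"{locus_sim.total_reads}\n")


def simulate_sample(truth: TruthProfile, panel: PanelConfig,
                    params: SimulationParams, fastq_path, manifest_path=None,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> SampleSim:
    """Simulate a single-source library and write FASTQ (+ manifest)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    sim = simulate_reads([(truth, params.input_pg)], panel, params, rng,
                         sample_id=truth.sample_id)
    write_fastq(sim, fastq_path)
    if manifest_path is not None:
        write_manifest(sim, manifest_path)
    return sim


def simulate_mixture(truth_a: TruthProfile, truth_b: TruthProfile, ratio: float,
                     panel: PanelConfig, params: SimulationParams,
                     fastq_path=None, seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     sample_id: str | None = None) -> SampleSim:
    """Simulate a two-person mixture with template ratio ``ratio``:1 (A:B)."""
    if ratio <= 0:
        raise ValueError("mixture ratio must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    pg_a = params.input_pg * ratio / (ratio + 1.0)
    pg_b = params.input_pg - pg_a
    sample_id = sample_id or f"{truth_a.sample_id}+{truth_b.sample_id}@{ratio}"
    sim = simulate_reads([(truth_a, pg_a), (truth_b, pg_b)], panel, params, rng,
                         sample_id=sample_id)
    if fastq_path is not None:
        write_fastq(sim, fastq_path)
    return sim


# ---------------------------------------------------------------------------
# Truth-profile generation
# ---------------------------------------------------------------------------

def _random_str_allele(locus: StrLocusDef, rng: np.random.Generator) -> TruthAllele:
    counts = []
    for block in locus.structure:
        lo, hi = block.min_count, block.max_count
        if hi - lo > 2:
            # keep generated alleles away from the extremes so that stutter
            # and drop-in products remain parseable under the structure
            lo, hi = lo + 1, hi - 1
        counts.append(lo if lo == hi else int(rng.integers(lo, hi + 1)))
    # canonicalize: when an optional separator block is absent, adjacent
    # same-motif blocks are unidentifiable from sequence, so store the
    # decomposition the parser reports for the generated sequence
    from .strtyping import _parse_cached
    canonical = _parse_cached(build_inner_sequence(locus.structure, tuple(counts)),
                              locus.structure)
    if canonical is not None:
        counts = list(canonical)
    return TruthAllele(tuple(counts))


def random_truth_profile(panel: PanelConfig, rng: np.random.Generator,
                         sample_id: str, sex: str | None = None,
                         het_rate: float = 0.85) -> TruthProfile:
    """Draw a panel-wide ground-truth profile with realistic heterozygosity."""
    if sex is None:
        sex = "M" if rng.random() < 0.5 else "F"
    str_alleles: dict[str, tuple[TruthAllele, ...]] = {}
    for locus in panel.str_loci:
        expected = locus.expected_allele_count(sex)
        if expected == 0:
            continue
        first = _random_str_allele(locus, rng)
        if expected == 1:
            str_alleles[locus.name] = (first,)
        else:
            if locus.ploidy_class == "Y" or rng.random() < het_rate:
                second = _random_str_allele(locus, rng)
            else:
                second = first
            str_alleles[locus.name] = (first, second)
    snp_genotypes: dict[str, tuple[str, str]] = {}
    for snp in panel.snp_loci:
        pair = tuple(snp.ref_allele if rng.random() < 0.5 else snp.alt_allele
                     for _ in range(2))
        snp_genotypes[snp.name] = (min(pair), max(pair))
    return TruthProfile(sample_id, sex, str_alleles, snp_genotypes)
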