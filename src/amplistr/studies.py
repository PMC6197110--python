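"""Evaluation study designs: reproducibility, concordance, sensitivity, mixtures.

Each runner exercises the full pipeline (simulate -> type -> call) and
tabulates the comparison statistics a laboratory validation reports:
duplicate genotype reproducibility with drop-in/drop-out classification,
concordance against length-based (CE) genotypes, drop-out counts across a
DNA dilution series, and the single-source indicator across a two-person
mixture series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calling import SampleProfile, call_sample, identify_stutter_relation
from .panel import PanelConfig
from .simulate import (SampleSim, SimulationParams, TruthProfile,
                       simulate_mixture, simulate_reads)
from .strtyping import assign_reads_to_loci, bracketed_name, ce_allele_number

__all__ = [
    "DiscordanceRecord", "ComparisonResult", "SensitivitySummary",
    "MixtureSummary", "compare_profiles", "ce_concordance",
    "run_reproducibility", "run_sensitivity", "run_mixture_series",
    "type_and_call",
]


def profile_from_genotypes(sample_id: str, sex: str,
                           str_genotypes: dict[str, list] | None = None,
                           snp_genotypes: dict[str, list] | None = None
                           ) -> SampleProfile:
    """Build a SampleProfile from externally typed genotype tables.

    ``str_genotypes`` maps locus name to a list of allele labels (a plain
    CE label, or a (ce_label, bracketed) pair); ``snp_genotypes`` maps an
    rs identifier to its called bases.  An empty list marks a locus that
    was typed but produced no call (a locus drop-out candidate).  Useful
    for comparing against report tables that did not pass through this
    pipeline's read-level typing.
    """
    from .calling import LocusCall
    from .strtyping import SequenceAllele
    calls: dict[str, LocusCall] = {}
    for locus, labels in (str_genotypes or {}).items():
        alleles = []
        for label in labels:
            ce, br = (label, str(label)) if isinstance(label, str) else label
            alleles.append(SequenceAllele(
                locus=locus, counts=(), ce_label=str(ce), bracketed=str(br),
                flank_variants=(), read_count=1, fraction_of_locus=0.0))
        calls[locus] = LocusCall(locus, "STR", "autosomal", called=alleles)
    for locus, bases in (snp_genotypes or {}).items():
        calls[locus] = LocusCall(locus, "SNP", None, called=list(bases),
                                 snp_category="HID")
    return SampleProfile(sample_id, sex, calls)


def type_and_call(sim: SampleSim, panel: PanelConfig,
                  sex: str | None = None) -> SampleProfile:
    """Assign a simulated sample's reads to loci and call the profile."""
    groups, _unassigned = assign_reads_to_loci(sim.pooled_reads(), panel)
    if sex is None and sim.truth is not None:
        sex = sim.truth.sex
    return call_sample(groups, panel, sim.sample_id, sex=sex)


# ---------------------------------------------------------------------------
# Profile comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscordanceRecord:
    sample: str
    locus: str
    category: str  # locus_dropout | allele_dropout | allele_dropin
    detail: str = ""


@dataclass
class ComparisonResult:
    compared: int
    concordant: int
    records: list[DiscordanceRecord] = field(default_factory=list)

    @property
    def rate(self) -> float:
        return self.concordant / self.compared if self.compared else 1.0

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.rate

    def __iadd__(self, other: "ComparisonResult") -> "ComparisonResult":
        self.compared += other.compared
        self.concordant += other.concordant
        self.records.extend(other.records)
        return self


def _call_keys(call) -> frozenset:
    if call is None or not call.is_called:
        return frozenset()
    if call.marker_type == "SNP":
        return frozenset(call.called)
    return frozenset((a.ce_label, a.bracketed,
                      tuple(str(v) for v in a.flank_variants))
                     for a in call.called)


def _stutter_like(extra_key, shared_keys, call) -> bool:
    """Is the extra allele an n-1 derivative of a concordant allele?"""
    if call is None or call.marker_type != "STR":
        return False
    by_key = {(a.ce_label, a.bracketed,
               tuple(str(v) for v in a.flank_variants)): a for a in call.called}
    extra = by_key.get(extra_key)
    if extra is None:
        return False
    for key in shared_keys:
        other = by_key.get(key)
        if other is None:
            continue
        rel = identify_stutter_relation(extra.counts, other.counts)
        if rel is not None and rel[0] == "n-1":
            return True
    return False


def compare_profiles(a: SampleProfile, b: SampleProfile) -> ComparisonResult:
    """Duplicate-typing comparison.

    Loci uncalled in both replicates are excluded from the denominator.
    A locus called in exactly one replicate is a locus drop-out.  An
    allele present in only one replicate is a drop-in when that replicate
    carries more alleles than the other *and* more than the locus's
    expected ploidy (a supernumerary allele); otherwise it is a drop-out
    of the other replicate.  Drop-ins that are n-1 derivatives of a
    shared allele are annotated as consistent with stutter.
    """
    loci = set(a.calls) | set(b.calls)
    if set(a.calls) and set(b.calls) and not loci:
        raise ValueError("profiles share no loci; panel mismatch?")
    result = ComparisonResult(0, 0)
    for locus in sorted(loci):
        ca, cb = a.calls.get(locus), b.calls.get(locus)
        ka, kb = _call_keys(ca), _call_keys(cb)
        if not ka and not kb:
            continue
        result.compared += 1
        if ka == kb:
            result.concordant += 1
            continue
        if not ka or not kb:
            result.records.append(DiscordanceRecord(
                a.sample_id, locus, "locus_dropout",
                "replicate A uncalled" if not ka else "replicate B uncalled"))
            continue
        shared = ka & kb
        expected_n = 1 if (ca.ploidy_class == "Y" or cb.ploidy_class == "Y") \
            else 2
        for key, owner_keys, owner_call, other_name in (
                [(k, kb, cb, "A") for k in sorted(kb - ka, key=str)]
                + [(k, ka, ca, "B") for k in sorted(ka - kb, key=str)]):
            other_keys = ka if owner_keys is kb else kb
            if len(owner_keys) > len(other_keys) and len(owner_keys) > expected_n:
                detail = ("consistent with stutter"
                          if _stutter_like(key, shared, owner_call) else "")
                result.records.append(DiscordanceRecord(
                    a.sample_id, locus, "allele_dropin", detail))
            else:
                result.records.append(DiscordanceRecord(
                    a.sample_id, locus, "allele_dropout",
                    f"allele absent from replicate {other_name}"))
    return result


def ce_concordance(profile: SampleProfile,
                   ce_table: dict[str, tuple[str, ...]]) -> ComparisonResult:
    """Concordance of sequence genotypes with length-based CE genotypes.

    Sequence alleles collapse to their CE labels before comparison, so a
    flanking-indel allele whose CE designation matches the fragment-length
    name is concordant by construction.  CE-table loci absent from the
    profile are skipped with a record.
    """
    result = ComparisonResult(0, 0)
    for locus, ce_genotype in sorted(ce_table.items()):
        call = profile.calls.get(locus)
        if call is None:
            result.records.append(DiscordanceRecord(
                profile.sample_id, locus, "locus_dropout", "absent from profile"))
            result.compared += 1
            continue
        seq_labels = frozenset(a.ce_label for a in call.called)
        ce_labels = frozenset(str(x) for x in ce_genotype)
        result.compared += 1
        if seq_labels == ce_labels:
            result.concordant += 1
        elif seq_labels > ce_labels:
            result.records.append(DiscordanceRecord(
                profile.sample_id, locus, "allele_dropin",
                "extra sequence allele vs CE"))
        elif seq_labels < ce_labels:
            result.records.append(DiscordanceRecord(
                profile.sample_id, locus, "allele_dropout",
                "sequence allele missing vs CE"))
        else:
            result.records.append(DiscordanceRecord(
                profile.sample_id, locus, "allele_dropin", "genotype mismatch"))
    return result


def run_reproducibility(truths: list[TruthProfile], panel: PanelConfig,
                        params: SimulationParams,
                        rng: np.random.Generator) -> ComparisonResult:
    """Duplicate library simulation and comparison for each truth profile."""
    total = ComparisonResult(0, 0)
    for truth in truths:
        profiles = []
        for rep in ("a", "b"):
            sim = simulate_reads([(truth, params.input_pg)], panel, params, rng,
                                 sample_id=f"{truth.sample_id}-{rep}")
            prof = type_and_call(sim, panel, sex=truth.sex)
            prof.sample_id = truth.sample_id
            profiles.append(prof)
        total += compare_profiles(profiles[0], profiles[1])
    return total


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

_CATEGORIES = ("autosomal_str", "y_str", "x_str_female", "x_str_male", "hid_snp")


@dataclass
class SensitivitySummary:
    input_pg: float
    replicates: int
    mean_correct: dict[str, float]
    mean_dropin: dict[str, float]
    mean_dropout: dict[str, float]
    mean_low_depth: dict[str, float]
    mean_imbalance: dict[str, float]

    @property
    def total_mean_dropout(self) -> float:
        return sum(self.mean_dropout.values())


def _truth_str_keys(truth: TruthProfile, locus) -> frozenset:
    keys = set()
    for a in truth.str_alleles.get(locus.name, ()):
        net = 0
        for kind, _side, _off, payload in a.flank_variants:
            if kind == "deletion":
                net -= int(payload)
            elif kind == "insertion":
                net += len(payload)
        ce = ce_allele_number(locus.structure, a.counts,
                              locus.canonical_motif_len, net)
        keys.add((ce, bracketed_name(locus.structure, a.counts), ()))
    return frozenset(keys)


def _category_of(locus, sex: str) -> str | None:
    if locus.ploidy_class == "autosomal":
        return "autosomal_str"
    if locus.ploidy_class == "Y":
        return "y_str" if sex == "M" else None
    return "x_str_female" if sex == "F" else "x_str_male"


def _classify_locus(called_keys: frozenset, truth_keys: frozenset) -> str:
    if called_keys == truth_keys:
        return "correct"
    if truth_keys - called_keys:
        return "dropout"
    return "dropin"


def run_sensitivity(truths: list[TruthProfile], dilutions_pg: list[float],
                    replicates: int, panel: PanelConfig,
                    params: SimulationParams,
                    rng: np.random.Generator) -> list[SensitivitySummary]:
    """Dilution series: simulate, type, call, compare to the truth.

    ``replicates`` samples are drawn per dilution level, cycling over the
    given truth profiles, and per-category mean counts of correct /
    drop-in / drop-out loci and of low-read-depth / imbalance warnings are
    tabulated.
    """
    summaries: list[SensitivitySummary] = []
    for pg in dilutions_pg:
        params_pg = replace(params, input_pg=float(pg))
        acc = {stat: {c: 0.0 for c in _CATEGORIES}
               for stat in ("correct", "dropin", "dropout", "low_depth",
                            "imbalance")}
        for rep in range(replicates):
            truth = truths[rep % len(truths)]
            sim = simulate_reads([(truth, float(pg))], panel, params_pg, rng,
                                 sample_id=f"{truth.sample_id}@{pg}pg#{rep}")
            profile = type_and_call(sim, panel, sex=truth.sex)
            for locus in panel.str_loci:
                cat = _category_of(locus, truth.sex)
                if cat is None:
                    continue
                call = profile.calls.get(locus.name)
                keys = _call_keys(call)
                truth_keys = _truth_str_keys(truth, locus)
                acc[_classify_locus(keys, truth_keys)][cat] += 1
                if call is not None:
                    kinds = call.alert_kinds()
                    acc["low_depth"][cat] += kinds.count("low_read_depth")
                    acc["imbalance"][cat] += kinds.count("imbalance")
            for snp in panel.snp_loci:
                if snp.category != "HID":
                    continue
                call = profile.calls.get(snp.name)
                keys = _call_keys(call)
                truth_keys = frozenset(truth.snp_genotypes.get(snp.name, ()))
                acc[_classify_locus(keys, truth_keys)]["hid_snp"] += 1
                if call is not None:
                    kinds = call.alert_kinds()
                    acc["low_depth"]["hid_snp"] += kinds.count("low_read_depth")
                    acc["imbalance"]["hid_snp"] += kinds.count("imbalance")
        summaries.append(SensitivitySummary(
            input_pg=float(pg), replicates=replicates,
            mean_correct={c: acc["correct"][c] / replicates for c in _CATEGORIES},
            mean_dropin={c: acc["dropin"][c] / replicates for c in _CATEGORIES},
            mean_dropout={c: acc["dropout"][c] / replicates for c in _CATEGORIES},
            mean_low_depth={c: acc["low_depth"][c] / replicates
                            for c in _CATEGORIES},
            mean_imbalance={c: acc["imbalance"][c] / replicates
                            for c in _CATEGORIES}))
    return summaries


# ---------------------------------------------------------------------------
# Mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureSummary:
    ratio: float  # contributor A templates per contributor B template
    verdicts: list[bool]  # single-source indicator per replicate
    mean_allele_count_alerts: float  # autosomal STR
    mean_str_imbalance_alerts: float  # autosomal STR
    mean_snp_imbalance_alerts: float  # HID SNP
    mean_y_alleles_detected: float

    @property
    def all_pass(self) -> bool:
        return all(self.verdicts)

    @property
    def all_fail(self) -> bool:
        return not any(self.verdicts)


def run_mixture_series(truth_a: TruthProfile, truth_b: TruthProfile,
                       ratios: list[float], replicates: int,
                       panel: PanelConfig, params: SimulationParams,
                       rng: np.random.Generator) -> list[MixtureSummary]:
    """Two-person mixture series through the full pipeline.

    For each template ratio A:B, ``replicates`` libraries are simulated,
    typed and classified with the single-source indicator; alert counts
    are averaged over replicates.
    """
    summaries: list[MixtureSummary] = []
    for ratio in ratios:
        verdicts: list[bool] = []
        ac_alerts: list[int] = []
        imb_alerts: list[int] = []
        snp_alerts: list[int] = []
        y_alleles: list[int] = []
        for rep in range(replicates):
            sim = simulate_mixture(truth_a, truth_b, ratio, panel, params,
                                   rng=rng, sample_id=f"mix{ratio}#{rep}")
            profile = type_and_call(sim, panel, sex=None)
            verdicts.append(profile.single_source)
            ac_alerts.append(profile.alert_count("allele_count", "STR",
                                                 ploidy_class="autosomal"))
            imb_alerts.append(profile.alert_count("imbalance", "STR",
                                                  ploidy_class="autosomal"))
            snp_alerts.append(profile.alert_count("imbalance", "SNP",
                                                  snp_category="HID"))
            y_alleles.append(sum(
                len(c.called) for c in profile.calls.values()
                if c.marker_type == "STR" and c.ploidy_class == "Y"))
        summaries.append(MixtureSummary(
            ratio=ratio, verdicts=verdicts,
            mean_allele_count_alerts=float(np.mean(ac_alerts)),
            mean_str_imbalance_alerts=float(np.mean(imb_alerts)),
            mean_snp_imbalance_alerts=float(np.mean(snp_alerts)),
            mean_y_alleles_detected=float(np.mean(y_alleles))))
    return summaries
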