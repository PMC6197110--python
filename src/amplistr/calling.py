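"""Threshold- and alert-based genotype calling with a mixture indicator.

Implements the interpretation layer of the evaluated analysis software:
depth-dependent interpretation (IT) and analytical (AT) thresholds,
structural stutter filtering at per-locus fixed percentages of the parent
allele, quality alerts (low read depth, imbalance, allele count, AT-zone
sequences) and the sample-level single-source indicator that counts
autosomal-STR and HID-SNP alert violations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .panel import PanelConfig, StrLocusDef, ThresholdSet
from .snptyping import SnpGenotype, call_snp_genotype, count_snp_alleles
from .strtyping import LocusReadGroup, SequenceAllele, report_sequence_alleles

__all__ = [
    "Alert", "LocusCall", "SampleProfile", "StutterObservation",
    "effective_thresholds", "identify_stutter_relation", "apply_stutter_filter",
    "raise_alerts", "classify_single_source", "call_str_locus", "call_sample",
    "infer_sex",
]


@dataclass(frozen=True)
class Alert:
    locus: str
    kind: str  # low_read_depth | imbalance | allele_count | at_zone
    detail: str = ""


@dataclass
class StutterObservation:
    """A filtered (or measured) stutter product tied to its parent allele."""

    locus: str
    parent: SequenceAllele
    stutter: SequenceAllele
    relation: str  # n-1 | n-2 | n+1
    slipped_block: int
    ambiguous_parent: bool = False

    @property
    def ratio(self) -> float:
        return self.stutter.read_count / self.parent.read_count

    @property
    def parent_reads(self) -> int:
        return self.parent.read_count

    @property
    def stutter_reads(self) -> int:
        return self.stutter.read_count


@dataclass
class LocusCall:
    locus: str
    marker_type: str  # "STR" | "SNP"
    ploidy_class: str | None
    called: list = field(default_factory=list)  # SequenceAllele | base str
    locus_depth: int = 0
    hb: float | None = None
    hb_flagged: bool = False
    alerts: list[Alert] = field(default_factory=list)
    filtered_stutters: list[StutterObservation] = field(default_factory=list)
    at_zone: list = field(default_factory=list)
    it: int = 0
    at: int = 0
    snp_genotype: SnpGenotype | None = None
    snp_category: str | None = None

    @property
    def is_called(self) -> bool:
        return bool(self.called)

    def alert_kinds(self) -> list[str]:
        return [a.kind for a in self.alerts]


def effective_thresholds(locus_depth: int,
                         thresholds: ThresholdSet) -> tuple[int, int]:
    """Depth-dependent (IT, AT) in reads.

    Below ``depth_switch`` locus reads the absolute settings apply; at or
    above it the user-defined fractions of the locus total apply, rounded
    up.
    """
    if locus_depth < 0:
        raise ValueError("locus_depth must be non-negative")
    if locus_depth < thresholds.depth_switch:
        return thresholds.it_absolute, thresholds.at_absolute
    return (math.ceil(thresholds.it_fraction * locus_depth),
            math.ceil(thresholds.at_fraction * locus_depth))


def identify_stutter_relation(candidate: tuple[int, ...],
                              parent: tuple[int, ...]) -> tuple[str, int] | None:
    """Slippage relation between two block-count vectors of one structure.

    Returns (relation, slipped block index) when the candidate differs
    from the parent in exactly one block by -1, -2 or +1 units, else None.
    Same-length stutters from compound repeats are distinguished by which
    block slipped.
    """
    if len(candidate) != len(parent):
        return None
    diffs = [(i, c - p) for i, (c, p) in enumerate(zip(candidate, parent))
             if c != p]
    if len(diffs) != 1:
        return None
    idx, d = diffs[0]
    if d == -1:
        return "n-1", idx
    if d == -2:
        return "n-2", idx
    if d == 1:
        return "n+1", idx
    return None


def _stutter_threshold(locus: StrLocusDef, relation: str) -> float:
    if relation == "n-1":
        return locus.stutter_threshold_n1
    if relation == "n-2":
        return locus.threshold_n2
    return locus.threshold_np1


def apply_stutter_filter(alleles: list[SequenceAllele], locus: StrLocusDef
                         ) -> tuple[list[SequenceAllele], list[StutterObservation]]:
    """Separate stutter products from allele candidates.

    A sequence is filtered as stutter iff it is a structural n-1/n-2/n+1
    derivative of a deeper retained sequence *and* its read count is at or
    below the locus threshold fraction of that parent's reads.  Sequences
    that merely sit at a stutter position but exceed the threshold are
    retained (and typically trigger an allele-count alert downstream);
    sequences not derivable from any retained allele are never filtered.
    With several consistent parents the deepest is chosen and the
    observation flagged ambiguous.
    """
    retained: list[SequenceAllele] = []
    stutters: list[StutterObservation] = []
    for cand in sorted(alleles, key=lambda a: -a.read_count):
        parents = []
        for parent in retained:
            rel = identify_stutter_relation(cand.counts, parent.counts)
            if rel is None:
                continue
            threshold = _stutter_threshold(locus, rel[0])
            if cand.read_count <= threshold * parent.read_count:
                parents.append((parent, rel))
        if parents:
            parents.sort(key=lambda pr: -pr[0].read_count)
            parent, (relation, idx) = parents[0]
            stutters.append(StutterObservation(
                locus.name, parent, cand, relation, idx,
                ambiguous_parent=len(parents) > 1))
        else:
            retained.append(cand)
    return retained, stutters


def _str_hb_of(called: list[SequenceAllele]) -> tuple[float | None, bool]:
    """Longest/shortest read-count ratio for a two-allele call.

    Isometric heterozygotes (equal length, different sequence) fall back
    to CE-label then bracketed-name ordering and are flagged.
    """
    if len(called) != 2:
        return None, False
    a, b = called
    la, lb = len(a.sequence), len(b.sequence)
    if la == lb:
        key = lambda x: (_ce_sort_key(x.ce_label), x.bracketed)
        longer, shorter = sorted([a, b], key=key, reverse=True)
        return longer.read_count / shorter.read_count, True
    longer, shorter = (a, b) if la > lb else (b, a)
    return longer.read_count / shorter.read_count, False


def _ce_sort_key(label: str) -> float:
    try:
        if "." in label:
            units, rem = label.split(".")
            return int(units) + int(rem) / 10.0
        return float(int(label))
    except ValueError:
        return 0.0


def raise_alerts(call: LocusCall, thresholds: ThresholdSet,
                 expected_alleles: int) -> list[Alert]:
    """Quality alerts for a finalized locus call."""
    alerts: list[Alert] = []
    if call.locus_depth < thresholds.low_depth_factor * thresholds.it_absolute:
        alerts.append(Alert(call.locus, "low_read_depth",
                            f"locus depth {call.locus_depth}"))
    elif not call.is_called:
        alerts.append(Alert(call.locus, "low_read_depth",
                            "no sequence above the interpretation threshold"))
    if call.hb is not None and not (thresholds.hb_alert_low <= call.hb
                                    <= thresholds.hb_alert_high):
        alerts.append(Alert(call.locus, "imbalance", f"Hb {call.hb:.2f}"))
    if expected_alleles and len(call.called) > expected_alleles:
        alerts.append(Alert(call.locus, "allele_count",
                            f"{len(call.called)} alleles retained"))
    for seq in call.at_zone:
        alerts.append(Alert(call.locus, "at_zone",
                            f"sequence at {seq.read_count} reads in [AT, IT]"))
    return alerts


def call_str_locus(group: LocusReadGroup, locus: StrLocusDef,
                   panel: PanelConfig, expected_alleles: int) -> LocusCall:
    """Full interpretation of one STR locus from its read group."""
    thresholds = panel.thresholds
    call = LocusCall(locus.name, "STR", locus.ploidy_class,
                     locus_depth=group.total_reads)
    call.it, call.at = effective_thresholds(group.total_reads, thresholds)
    reported = report_sequence_alleles(group, locus, panel)
    retained, stutters = apply_stutter_filter(reported, locus)
    call.filtered_stutters = stutters
    call.called = [a for a in retained if a.read_count > call.it]
    call.at_zone = [a for a in retained
                    if call.at <= a.read_count <= call.it]
    call.hb, call.hb_flagged = _str_hb_of(call.called)
    call.alerts = raise_alerts(call, thresholds, expected_alleles)
    return call


def call_snp_locus(group: LocusReadGroup, locus, panel: PanelConfig) -> LocusCall:
    thresholds = panel.thresholds
    obs = count_snp_alleles(group, locus)
    geno = call_snp_genotype(obs, thresholds)
    call = LocusCall(locus.name, "SNP", None, locus_depth=obs.total_reads,
                     snp_genotype=geno, snp_category=locus.category)
    call.called = list(geno.alleles)
    call.hb = geno.hb
    alerts: list[Alert] = []
    if obs.total_reads < thresholds.low_depth_factor * thresholds.it_absolute:
        alerts.append(Alert(locus.name, "low_read_depth",
                            f"locus depth {obs.total_reads}"))
    elif not geno.called:
        alerts.append(Alert(locus.name, "low_read_depth",
                            "no base above the allele minimum"))
    if geno.hb is not None and not (thresholds.hb_alert_low <= geno.hb
                                    <= thresholds.hb_alert_high):
        alerts.append(Alert(locus.name, "imbalance", f"Hb {geno.hb:.2f}"))
    if geno.extra_alleles:
        alerts.append(Alert(locus.name, "allele_count",
                            f"{len(geno.extra_alleles)} bases above the minimum"))
    call.alerts = alerts
    return call


@dataclass
class SampleProfile:
    sample_id: str
    sex: str
    calls: dict[str, LocusCall]
    single_source: bool = True
    str_violations: float = 0.0
    snp_violations: float = 0.0

    def str_calls(self) -> list[LocusCall]:
        return [c for c in self.calls.values() if c.marker_type == "STR"]

    def snp_calls(self) -> list[LocusCall]:
        return [c for c in self.calls.values() if c.marker_type == "SNP"]

    def alert_count(self, kind: str, marker_type: str = "STR",
                    ploidy_class: str | None = None,
                    snp_category: str | None = None) -> int:
        n = 0
        for c in self.calls.values():
            if c.marker_type != marker_type:
                continue
            if ploidy_class is not None and c.ploidy_class != ploidy_class:
                continue
            if snp_category is not None and c.snp_category != snp_category:
                continue
            n += sum(1 for a in c.alerts if a.kind == kind)
        return n


def classify_single_source(profile: SampleProfile,
                           thresholds: ThresholdSet) -> bool:
    """Single-source indicator from alert violations.

    STR violations sum imbalance and allele-count alerts over the
    autosomal STRs; SNP violations count imbalance alerts over the HID
    SNPs (AIM and phenotype SNPs are excluded).  The sample passes as
    single-source iff both totals stay within their limits; violations
    strictly above a limit fail the sample.
    """
    str_v = (profile.alert_count("imbalance", "STR", ploidy_class="autosomal")
             + profile.alert_count("allele_count", "STR", ploidy_class="autosomal"))
    snp_v = profile.alert_count("imbalance", "SNP", snp_category="HID")
    profile.str_violations = float(str_v)
    profile.snp_violations = float(snp_v)
    ok = classify_single_source_counts(str_v, snp_v, thresholds)
    profile.single_source = ok
    return ok


def classify_single_source_counts(str_violations: float, snp_violations: float,
                                  thresholds: ThresholdSet) -> bool:
    """The indicator rule on pre-computed violation counts (possibly
    replicate averages): pass iff STR violations <= the STR limit AND SNP
    violations <= the SNP limit."""
    return (str_violations <= thresholds.str_violation_limit
            and snp_violations <= thresholds.snp_violation_limit)


def infer_sex(groups: dict[str, LocusReadGroup], panel: PanelConfig) -> str:
    """Male iff at least half of the Y STR loci received reads."""
    y_loci = [l.name for l in panel.str_loci if l.ploidy_class == "Y"]
    if not y_loci:
        return "F"
    with_reads = sum(1 for n in y_loci if groups[n].total_reads > 0)
    return "M" if with_reads >= len(y_loci) / 2 else "F"


def call_sample(groups: dict[str, LocusReadGroup], panel: PanelConfig,
                sample_id: str, sex: str | None = None) -> SampleProfile:
    """Interpret all loci of one sample and apply the mixture indicator."""
    if sex is None:
        sex = infer_sex(groups, panel)
    calls: dict[str, LocusCall] = {}
    for locus in panel.str_loci:
        expected = locus.expected_allele_count(sex)
        if expected == 0 and groups[locus.name].total_reads == 0:
            continue  # female profile, silent Y locus
        calls[locus.name] = call_str_locus(groups[locus.name], locus, panel,
                                           expected or locus.n_amplicons)
    for snp in panel.snp_loci:
        calls[snp.name] = call_snp_locus(groups[snp.name], snp, panel)
    profile = SampleProfile(sample_id, sex, calls)
    classify_single_source(profile, panel.thresholds)
    return profile
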