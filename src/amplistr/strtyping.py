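"""Flank-anchored STR typing: read sorting, repeat parsing and nomenclature.

Reads are assigned to loci by locating both locus flanks within a bounded
edit-distance budget; the sequence between the flanks is decomposed into
the locus's ordered motif blocks, named in bracketed form and given a
length-based (CE) designation.  Variants in the flanking sequences are
detected by alignment against the reference flank and reported with GRCh37
coordinates alongside the repeat allele.

The mismatch budget counts substitutions individually and each contiguous
indel run as a single event, so a genuine multi-base flanking deletion
(e.g. the 13 bp deletion upstream of Penta D) costs one event rather than
thirteen.  Because an indel that abuts the repeat region is ambiguous at
the edit-distance level, the flank/repeat boundary is refined by requiring
the inner sequence to decompose into whole motif blocks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache

import edlib

from .panel import MotifBlock, PanelConfig, StrLocusDef

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceAllele", "FlankVariant", "LocusReadGroup", "ParseError",
    "assign_reads_to_loci", "parse_repeat_structure", "ce_allele_number",
    "detect_flank_variants", "report_sequence_alleles", "bracketed_name",
    "build_inner_sequence", "full_allele_name",
]

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


class ParseError(ValueError):
    """A repeat region that cannot be decomposed under the locus structure."""


# ---------------------------------------------------------------------------
# Nomenclature
# ---------------------------------------------------------------------------

def ce_allele_number(structure, counts, canonical_motif_len: int,
                     net_flank_indel_bases: int = 0) -> str:
    """Length-based (CE) allele designation.

    The adjusted repeat length is the number of counting-block units times
    the canonical motif length, plus the bases of any partial blocks, plus
    the net insertion/deletion length observed in the analysed flanking
    range (CE sees fragment length, so flanking indels shift the name).
    The label is ``units`` or ``units.remainder``.
    """
    if canonical_motif_len < 1:
        raise ValueError("canonical_motif_len must be >= 1")
    bases = 0
    for block, count in zip(structure, counts, strict=True):
        if block.ce_role == "unit":
            bases += count * canonical_motif_len
        elif block.ce_role == "partial":
            bases += count * len(block.motif)
    adjusted = bases + net_flank_indel_bases
    if adjusted < 0:
        raise ValueError(
            f"adjusted repeat length {adjusted} is negative "
            f"(net flank indel {net_flank_indel_bases})")
    units, rem = divmod(adjusted, canonical_motif_len)
    return f"{units}.{rem}" if rem else f"{units}"


def bracketed_name(structure, counts) -> str:
    """Bracketed sequence nomenclature, e.g. ``[AGAT]12 [AGAC]9``."""
    parts = []
    for block, count in zip(structure, counts, strict=True):
        if count == 0:
            continue
        parts.append(f"[{block.motif}]{count}")
    return " ".join(parts)


def build_inner_sequence(structure, counts) -> str:
    return "".join(b.motif * c for b, c in zip(structure, counts, strict=True))


def total_units(structure, counts) -> int:
    return sum(c for b, c in zip(structure, counts, strict=True)
               if b.ce_role == "unit")


# ---------------------------------------------------------------------------
# Repeat-region parsing
# ---------------------------------------------------------------------------

def _parse_blocks(seq: str, blocks: tuple[MotifBlock, ...]) -> tuple[int, ...] | None:
    """Greedy left-to-right decomposition with backtracking.

    Each ordered block consumes between ``min_count`` and ``max_count``
    copies of its motif; larger counts in earlier blocks are preferred,
    which matches the bracketed convention for compound repeats.  Returns
    per-block counts, or None when the sequence cannot be decomposed.
    """
    n_blocks = len(blocks)
    seen: dict[tuple[int, int], None] = {}

    def solve(bi: int, pos: int) -> tuple[int, ...] | None:
        if bi == n_blocks:
            return () if pos == len(seq) else None
        if (bi, pos) in seen:
            return None
        block = blocks[bi]
        motif, mlen = block.motif, len(block.motif)
        avail = 0
        p = pos
        while avail < block.max_count and seq.startswith(motif, p):
            avail += 1
            p += mlen
        for count in range(avail, block.min_count - 1, -1):
            rest = solve(bi + 1, pos + count * mlen)
            if rest is not None:
                return (count,) + rest
        seen[(bi, pos)] = None
        return None

    return solve(0, 0)


# cross-sample memo: allele and stutter inner sequences recur constantly
@lru_cache(maxsize=500_000)
def _parse_cached(seq: str, structure: tuple[MotifBlock, ...]):
    return _parse_blocks(seq, structure)


def parse_repeat_structure(seq: str, locus: StrLocusDef) -> tuple[tuple[int, ...], int]:
    """Decompose a repeat-region sequence into the locus's ordered blocks.

    Returns (per-block counts, number of counting-block units).  Raises
    :class:`ParseError` when the sequence does not fit the structure; the
    caller tallies such reads as unparseable rather than dropping them
    silently.
    """
    if not seq:
        raise ParseError(f"{locus.name}: empty repeat region")
    counts = _parse_cached(seq, locus.structure)
    if counts is None:
        raise ParseError(f"{locus.name}: sequence does not fit repeat structure")
    return counts, total_units(locus.structure, counts)


# ---------------------------------------------------------------------------
# Flank variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankVariant:
    kind: str  # substitution | deletion | insertion
    ref_start: int  # 1-based GRCh37
    ref_end: int
    observed: str  # empty for deletion
    side: str  # upstream | downstream
    ambiguous: bool = False

    def __str__(self) -> str:
        if self.kind == "deletion":
            return f"del:{self.ref_start}-{self.ref_end}"
        if self.kind == "insertion":
            return f"ins:{self.ref_start}+{self.observed}"
        return f"sub:{self.ref_start}{self.observed}"


def _cigar_ops(cigar: str):
    for m in _CIG_RE.finditer(cigar):
        yield int(m.group(1)), m.group(2)


def detect_flank_variants(observed: str, reference: str, ref_origin: int,
                          side: str) -> list[FlankVariant]:
    """Minimal edit transcript between observed and reference flank,
    expressed as GRCh37-anchored variants.

    ``ref_origin`` is the 1-based coordinate of the first reference-flank
    base.  Equal-cost alignments resolve to the leftmost placement;
    deletions that could shift within a repeated context are flagged
    ambiguous.
    """
    if observed == reference:
        return []
    res = edlib.align(observed, reference, mode="NW", task="path")
    variants: list[FlankVariant] = []
    rpos = 0  # 0-based offset into the reference flank
    opos = 0
    run_del_start: int | None = None
    run_ins: list[str] = []
    ins_anchor = 0

    def flush_del(end_rpos: int) -> None:
        nonlocal run_del_start
        if run_del_start is not None:
            del_len = end_rpos - run_del_start
            seg = reference[run_del_start:end_rpos]
            nxt = reference[end_rpos:end_rpos + del_len]
            variants.append(FlankVariant(
                "deletion", ref_origin + run_del_start, ref_origin + end_rpos - 1,
                "", side, ambiguous=(bool(seg) and seg == nxt)))
            run_del_start = None

    def flush_ins(anchor_rpos: int) -> None:
        nonlocal run_ins
        if run_ins:
            anchor = ref_origin + ins_anchor - 1
            variants.append(FlankVariant("insertion", anchor, anchor,
                                         "".join(run_ins), side))
            run_ins = []

    for length, op in _cigar_ops(res["cigar"]):
        if op in ("=", "M"):
            flush_del(rpos)
            flush_ins(rpos)
            rpos += length
            opos += length
        elif op == "X":
            flush_del(rpos)
            flush_ins(rpos)
            for i in range(length):
                variants.append(FlankVariant(
                    "substitution", ref_origin + rpos + i, ref_origin + rpos + i,
                    observed[opos + i], side))
            rpos += length
            opos += length
        elif op == "I":  # present in observed, absent from reference -> insertion
            if not run_ins:
                ins_anchor = rpos
            run_ins.append(observed[opos:opos + length])
            opos += length
        elif op == "D":  # present in reference, absent from observed -> deletion
            if run_del_start is None:
                run_del_start = rpos
            rpos += length
    flush_del(rpos)
    flush_ins(rpos)
    return variants


def net_indel_bases(variants) -> int:
    net = 0
    for v in variants:
        if v.kind == "deletion":
            net -= v.ref_end - v.ref_start + 1
        elif v.kind == "insertion":
            net += len(v.observed)
    return net


# ---------------------------------------------------------------------------
# Read splitting (flank location + boundary refinement)
# ---------------------------------------------------------------------------

#: extra edit-distance headroom when *locating* a flank, so that genuine
#: indel variants (one mismatch event each) can still anchor
_INDEL_HEADROOM = 16
_PREFIX_LEN = 12


@lru_cache(maxsize=500_000)
def _nw_events(observed: str, reference: str) -> int:
    """Mismatch events between an observed and a reference flank:
    substitutions count singly, each contiguous indel run counts once."""
    if observed == reference:
        return 0
    res = edlib.align(observed, reference, mode="NW", task="path")
    events = 0
    prev_indel = False
    for length, op in _cigar_ops(res["cigar"]):
        if op == "X":
            events += length
            prev_indel = False
        elif op in ("I", "D"):
            if not prev_indel:
                events += 1
            prev_indel = True
        else:
            prev_indel = False
    return events


@dataclass(frozen=True)
class _Split:
    i: int  # inner start in read
    j: int  # inner end (exclusive)
    counts: tuple[int, ...] | None  # None = STR repeat region unparseable
    events_up: int
    events_down: int

    @property
    def events(self) -> int:
        return self.events_up + self.events_down


def _locate_up(read: str, up: str, k: int) -> tuple[int, int] | None:
    r = edlib.align(up, read, mode="SHW", task="locations", k=k)
    if r["editDistance"] < 0:
        return None
    return r["locations"][0][1] + 1, r["editDistance"]


def _locate_down(read: str, down: str, k: int) -> tuple[int, int] | None:
    r = edlib.align(down[::-1], read[::-1], mode="SHW", task="locations", k=k)
    if r["editDistance"] < 0:
        return None
    return len(read) - (r["locations"][0][1] + 1), r["editDistance"]


@lru_cache(maxsize=500_000)
def _split_and_parse(read: str, locus, allow_indel: bool = True) -> _Split | None:
    """Split ``read`` into (upstream flank, inner, downstream flank) for
    ``locus`` and parse the inner region when the locus is an STR.

    Stage one locates both flanks within the plain mismatch budget
    (substitution-dominated noise).  Only when that fails — and the
    caller has independent evidence the read belongs here
    (``allow_indel``) — is the search widened so that multi-base flanking
    indels, counted as single mismatch events, can still anchor.
    Returns None when either flank exceeds the locus mismatch budget.
    """
    up, down = locus.upstream_flank, locus.downstream_flank
    budget = locus.max_flank_mismatches
    is_str = isinstance(locus, StrLocusDef)

    def try_parse(i: int, j: int):
        if not is_str:
            return None
        return _parse_cached(read[i:j], locus.structure)

    # exact fast path
    if read.startswith(up) and read.endswith(down) and len(read) > len(up) + len(down):
        i, j = len(up), len(read) - len(down)
        return _Split(i, j, try_parse(i, j), 0, 0)

    loc_up = _locate_up(read, up, budget)
    loc_down = _locate_down(read, down, budget)
    if loc_up is not None and loc_down is not None:
        i0, ev_up = loc_up
        j0, ev_down = loc_down
        if i0 <= j0:
            return _Split(i0, j0, try_parse(i0, j0), ev_up, ev_down)
        return None
    if not allow_indel:
        return None

    # escalation: one or both flanks may carry an indel variant
    k = budget + _INDEL_HEADROOM
    wide_up = _locate_up(read, up, k)
    wide_down = _locate_down(read, down, k)
    if wide_up is None or wide_down is None or wide_up[0] > wide_down[0]:
        return None
    i0, j0 = wide_up[0], wide_down[0]
    ev_up = _nw_events(read[:i0], up)
    ev_down = _nw_events(read[j0:], down)
    counts = try_parse(i0, j0)
    if ev_up <= budget and ev_down <= budget:
        if counts is not None or not is_str:
            return _Split(i0, j0, counts, ev_up, ev_down)
    if not is_str:
        return None

    # Boundary refinement: an indel adjacent to the repeat region is
    # ambiguous at the edit-distance level, so slide the failing boundary
    # until the inner sequence decomposes into whole motif blocks.  The
    # boundaries are scanned in maximal-repeat-span order, following the
    # convention that the repeat region is kept maximal and indels are
    # placed in the flank.
    if (counts is None or ev_up > budget or ev_down > budget) and \
            (ev_up <= budget) != (ev_down <= budget):
        if ev_up > budget:
            for i in range(max(0, i0 - _INDEL_HEADROOM),
                           min(j0, i0 + _INDEL_HEADROOM) + 1):
                c = _parse_cached(read[i:j0], locus.structure)
                if c is None:
                    continue
                ev = _nw_events(read[:i], up)
                if ev <= budget:
                    return _Split(i, j0, c, ev, ev_down)
        else:
            for j in range(min(len(read), j0 + _INDEL_HEADROOM),
                           max(i0, j0 - _INDEL_HEADROOM) - 1, -1):
                c = _parse_cached(read[i0:j], locus.structure)
                if c is None:
                    continue
                ev = _nw_events(read[j:], down)
                if ev <= budget:
                    return _Split(i0, j, c, ev_up, ev)
    # flanks within budget but repeat region unparseable -> keep, tallied
    if ev_up <= budget and ev_down <= budget:
        return _Split(i0, j0, None, ev_up, ev_down)
    return None


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

@dataclass
class LocusReadGroup:
    """Reads assigned to one locus, collapsed to unique sequences."""

    locus: str
    total_reads: int = 0
    sequences: dict = field(default_factory=dict)  # read -> [count, _Split]
    unparseable_reads: int = 0

    def add(self, read: str, split: _Split, count: int) -> None:
        entry = self.sequences.get(read)
        if entry is None:
            self.sequences[read] = [count, split]
        else:
            entry[0] += count
        self.total_reads += count
        if split.counts is None:
            self.unparseable_reads += count


def assign_reads_to_loci(reads, panel: PanelConfig,
                         loci=None) -> tuple[dict[str, LocusReadGroup], int]:
    """Sort reads into loci by their flanking sequences.

    ``reads`` is an iterable of sequences or ``(sequence, count)`` pairs
    (identical reads may be pre-collapsed).  A read is assigned to a locus
    iff both flanks are found, each within the locus's per-flank mismatch
    budget; when several loci match, the smallest total mismatch count
    wins and exact ties are left unassigned.  Returns
    (locus name -> LocusReadGroup, unassigned read count).
    """
    if loci is None:
        loci = list(panel.str_loci) + list(panel.snp_loci)
    prefix_index: dict[str, list] = {}
    suffix_index: dict[str, list] = {}
    for locus in loci:
        prefix_index.setdefault(locus.upstream_flank[:_PREFIX_LEN], []).append(locus)
        suffix_index.setdefault(locus.downstream_flank[-_PREFIX_LEN:],
                                []).append(locus)
    groups = {l.name: LocusReadGroup(l.name) for l in loci}
    unassigned = 0
    n_in = 0
    for item in reads:
        if isinstance(item, tuple):
            read, count = item
        else:
            read, count = item, 1
        n_in += count
        best = None
        best_locus = None
        tied = False
        # identify candidates by intact outer anchors (upstream prefix or
        # downstream suffix); a full panel scan without indel escalation
        # is the fallback for doubly damaged anchors
        anchored: list = list(prefix_index.get(read[:_PREFIX_LEN], ()))
        for locus in suffix_index.get(read[-_PREFIX_LEN:], ()):
            if locus not in anchored:
                anchored.append(locus)
        candidates = anchored or loci
        allow_indel = bool(anchored)
        for locus in candidates:
            split = _split_and_parse(read, locus, allow_indel)
            if split is None:
                continue
            if best is None or split.events < best.events:
                best, best_locus, tied = split, locus, False
            elif split.events == best.events and locus is not best_locus:
                tied = True
        if best is None or tied:
            unassigned += count
        else:
            groups[best_locus.name].add(read, best, count)
    if n_in == 0:
        logger.warning("assign_reads_to_loci: empty input")
    return groups, unassigned


# ---------------------------------------------------------------------------
# Sequence alleles
# ---------------------------------------------------------------------------

@dataclass
class SequenceAllele:
    """A unique observed sequence at an STR locus, named and counted."""

    locus: str
    counts: tuple[int, ...]
    ce_label: str
    bracketed: str
    flank_variants: tuple[FlankVariant, ...]
    read_count: int
    fraction_of_locus: float
    units: int = 0
    sequence: str = ""

    @property
    def name(self) -> str:
        return full_allele_name(self)


def full_allele_name(allele: SequenceAllele) -> str:
    """Full sequence-allele name: CE label, bracketed blocks and variants."""
    parts = [f"{allele.locus}[CE{allele.ce_label}]", allele.bracketed]
    parts.extend(str(v) for v in allele.flank_variants)
    return " ".join(p for p in parts if p)


def report_sequence_alleles(group: LocusReadGroup, locus: StrLocusDef,
                            panel: PanelConfig) -> list[SequenceAllele]:
    """Sequences above the reporting fraction, parsed and named.

    Only sequences with read counts strictly above ``reporting_fraction``
    of the locus total are emitted (the denominator includes unparseable
    reads).  Output is sorted by descending read count.
    """
    thr = panel.thresholds.reporting_fraction * group.total_reads
    out: list[SequenceAllele] = []
    up_origin = locus.ref_start - len(locus.upstream_flank)
    down_origin = locus.ref_end + 1
    for read, (count, split) in group.sequences.items():
        if count <= thr or split.counts is None:
            continue
        variants: list[FlankVariant] = []
        obs_up, obs_down = read[:split.i], read[split.j:]
        if obs_up != locus.upstream_flank:
            variants.extend(detect_flank_variants(
                obs_up, locus.upstream_flank, up_origin, "upstream"))
        if obs_down != locus.downstream_flank:
            variants.extend(detect_flank_variants(
                obs_down, locus.downstream_flank, down_origin, "downstream"))
        ce = ce_allele_number(locus.structure, split.counts,
                              locus.canonical_motif_len, net_indel_bases(variants))
        out.append(SequenceAllele(
            locus=locus.name, counts=split.counts, ce_label=ce,
            bracketed=bracketed_name(locus.structure, split.counts),
            flank_variants=tuple(variants), read_count=count,
            fraction_of_locus=count / group.total_reads if group.total_reads else 0.0,
            units=total_units(locus.structure, split.counts), sequence=read))
    out.sort(key=lambda a: (-a.read_count, a.sequence))
    return out
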