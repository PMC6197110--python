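"""Marker panel definitions: STR/SNP loci, repeat structures and thresholds.

A panel couples locus identities (flanking sequences, repeat structure or
SNP alleles, GRCh37 coordinates) with the interpretation parameters of the
calling pipeline.  The bundled default panel mirrors a commercial forensic
multiplex: 27 autosomal STRs, 7 X-STRs, 24 Y-STRs and 94 human-identification
(HID) SNPs plus ancestry (AIM) and phenotype SNP sets.  Flanking sequences
for loci whose amplicon context is not publicly printed are panel-realistic
synthetic placeholders generated deterministically from the locus name.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "MotifBlock",
    "StrLocusDef",
    "SnpLocusDef",
    "ThresholdSet",
    "PanelConfig",
    "PanelError",
    "load_panel",
    "save_panel",
    "default_panel",
    "validate_flank_budget",
    "DEFAULT_FLANK_MISMATCH_BUDGET",
]

DNA = set("ACGT")

#: global default for the per-flank mismatch budget (substitutions plus
#: contiguous indel events); individual loci may override it upward when
#: their primer-proximal sequence is known to be error prone.
DEFAULT_FLANK_MISMATCH_BUDGET = 3


class PanelError(ValueError):
    """Raised for invalid or inconsistent panel configuration."""


@dataclass(frozen=True)
class MotifBlock:
    """One ordered block of a bracketed repeat structure.

    ``ce_role`` controls how the block enters length-based (CE) naming:
    ``unit`` blocks contribute whole repeat units, ``partial`` blocks
    contribute their bases to the fractional part (e.g. a trailing [AG]
    giving a ``.2`` allele), and ``none`` blocks are fixed intervening
    sequence ignored by the CE count (e.g. the [TA]/[TCA] spacers of
    D21S11).
    """

    motif: str
    min_count: int = 0
    max_count: int = 30
    ce_role: str = "unit"  # unit | partial | none

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - DNA:
            raise PanelError(f"motif must be non-empty A/C/G/T, got {self.motif!r}")
        if self.ce_role not in ("unit", "partial", "none"):
            raise PanelError(f"bad ce_role {self.ce_role!r}")
        if self.ce_role == "unit" and not 1 <= len(self.motif) <= 6:
            raise PanelError(f"counting motif must be 1-6 bases, got {self.motif!r}")
        if self.min_count < 0 or self.min_count > self.max_count:
            raise PanelError(
                f"bad count bounds [{self.min_count}, {self.max_count}] for {self.motif}"
            )

    @property
    def counts_toward_ce(self) -> bool:
        return self.ce_role != "none"


@dataclass(frozen=True)
class StrLocusDef:
    name: str
    chromosome: str
    ref_start: int  # 1-based inclusive GRCh37 start of the analysed repeat range
    ref_end: int
    upstream_flank: str
    downstream_flank: str
    structure: tuple[MotifBlock, ...]
    canonical_motif_len: int
    ploidy_class: str  # autosomal | X | Y
    max_flank_mismatches: int = DEFAULT_FLANK_MISMATCH_BUDGET
    n_amplicons: int = 1
    stutter_threshold_n1: float = 0.15
    stutter_threshold_n2: float | None = None  # defaults to half of n-1
    stutter_threshold_np1: float | None = None

    def __post_init__(self) -> None:
        if not self.upstream_flank or not self.downstream_flank:
            raise PanelError(f"{self.name}: flanks must be non-empty")
        if self.ploidy_class not in ("autosomal", "X", "Y"):
            raise PanelError(f"{self.name}: bad ploidy_class {self.ploidy_class!r}")
        if not 1 <= self.canonical_motif_len <= 6:
            raise PanelError(f"{self.name}: canonical_motif_len must be 1-6")
        if self.n_amplicons not in (1, 2):
            raise PanelError(f"{self.name}: n_amplicons must be 1 or 2")
        if self.max_flank_mismatches < 0:
            raise PanelError(f"{self.name}: negative flank mismatch budget")
        for thr in (self.stutter_threshold_n1, self.threshold_n2, self.threshold_np1):
            if not 0.0 <= thr <= 1.0:
                raise PanelError(f"{self.name}: stutter threshold {thr} outside [0, 1]")
        if not self.structure:
            raise PanelError(f"{self.name}: empty repeat structure")

    @property
    def threshold_n2(self) -> float:
        if self.stutter_threshold_n2 is not None:
            return self.stutter_threshold_n2
        return self.stutter_threshold_n1 / 2.0

    @property
    def threshold_np1(self) -> float:
        if self.stutter_threshold_np1 is not None:
            return self.stutter_threshold_np1
        return self.stutter_threshold_n1 / 2.0

    @property
    def hemizygous(self) -> bool:
        return self.ploidy_class == "Y"

    def expected_allele_count(self, sex: str) -> int:
        """Number of alleles expected in a single-source sample of ``sex``."""
        if self.ploidy_class == "autosomal":
            return 2
        if self.ploidy_class == "X":
            return 2 if sex == "F" else 1
        return 0 if sex == "F" else self.n_amplicons


@dataclass(frozen=True)
class SnpLocusDef:
    name: str  # rs identifier
    chromosome: str
    position: int  # 1-based GRCh37
    upstream_flank: str
    downstream_flank: str
    ref_allele: str
    alt_allele: str
    category: str  # HID | AIM | phenotype
    max_flank_mismatches: int = DEFAULT_FLANK_MISMATCH_BUDGET

    def __post_init__(self) -> None:
        if self.ref_allele not in DNA or self.alt_allele not in DNA:
            raise PanelError(f"{self.name}: alleles must be single A/C/G/T bases")
        if self.ref_allele == self.alt_allele:
            raise PanelError(f"{self.name}: ref and alt alleles are identical")
        if self.category not in ("HID", "AIM", "phenotype"):
            raise PanelError(f"{self.name}: bad category {self.category!r}")
        if not self.upstream_flank or not self.downstream_flank:
            raise PanelError(f"{self.name}: flanks must be non-empty")


@dataclass(frozen=True)
class ThresholdSet:
    """Interpretation parameters shared by the whole panel.

    ``it``/``at`` are the interpretation and analytical thresholds.  Below
    ``depth_switch`` locus reads they are the absolute read counts
    ``it_absolute``/``at_absolute``; at or above it they are the fractions
    ``it_fraction``/``at_fraction`` of the locus read total (rounded up).
    The single-source indicator tolerates up to ``str_violation_limit``
    summed autosomal-STR imbalance + allele-count alerts and up to
    ``snp_violation_limit`` HID-SNP imbalance alerts.
    """

    it_absolute: int = 30
    at_absolute: int = 10
    depth_switch: int = 650
    it_fraction: float = 0.045
    at_fraction: float = 0.015
    hb_alert_low: float = 0.5
    hb_alert_high: float = 2.0
    reporting_fraction: float = 0.01
    snp_min_allele_reads: int = 20
    str_violation_limit: float = 6.0
    snp_violation_limit: float = 11.0
    low_depth_factor: int = 2  # low-read-depth alert below factor * it_absolute reads

    def __post_init__(self) -> None:
        if self.at_absolute > self.it_absolute:
            raise PanelError("at_absolute must not exceed it_absolute")
        if not 0.0 < self.reporting_fraction < 1.0:
            raise PanelError("reporting_fraction must lie in (0, 1)")
        if not self.hb_alert_low < 1.0 < self.hb_alert_high:
            raise PanelError("hb alert bounds must bracket 1.0")


@dataclass
class PanelConfig:
    name: str
    str_loci: list[StrLocusDef] = field(default_factory=list)
    snp_loci: list[SnpLocusDef] = field(default_factory=list)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    version: str = "1"

    def __post_init__(self) -> None:
        names = [l.name for l in self.str_loci] + [l.name for l in self.snp_loci]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate locus name(s): {sorted(dupes)}")

    # -- census queries -------------------------------------------------
    def str_count(self, ploidy_class: str | None = None) -> int:
        if ploidy_class is None:
            return len(self.str_loci)
        return sum(1 for l in self.str_loci if l.ploidy_class == ploidy_class)

    def snp_count(self, category: str | None = None) -> int:
        if category is None:
            return len(self.snp_loci)
        return sum(1 for l in self.snp_loci if l.category == category)

    def str_locus(self, name: str) -> StrLocusDef:
        for l in self.str_loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def snp_locus(self, name: str) -> SnpLocusDef:
        for l in self.snp_loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def str_loci_for_sex(self, sex: str) -> list[StrLocusDef]:
        """Loci with at least one expected allele for a donor of ``sex``."""
        return [l for l in self.str_loci if l.expected_allele_count(sex) > 0]

    def to_bed(self) -> str:
        """Locus table as BED (0-based half-open) for interoperability."""
        rows = []
        for l in self.str_loci:
            rows.append(f"{l.chromosome}\t{l.ref_start - 1}\t{l.ref_end}\t{l.name}")
        for s in self.snp_loci:
            rows.append(f"{s.chromosome}\t{s.position - 1}\t{s.position}\t{s.name}")
        return "\n".join(rows) + "\n"


def validate_flank_budget(locus: StrLocusDef | SnpLocusDef) -> dict:
    """Report whether a locus overrides the global flank mismatch budget.

    A handful of loci need more than the default three mismatches because
    their flanks carry recurrent sequencing errors or true variants.
    """
    if locus.max_flank_mismatches < 0:  # defensive; dataclass already rejects
        raise PanelError(f"{locus.name}: negative flank mismatch budget")
    elevated = locus.max_flank_mismatches > DEFAULT_FLANK_MISMATCH_BUDGET
    return {
        "locus": locus.name,
        "budget": locus.max_flank_mismatches,
        "default": DEFAULT_FLANK_MISMATCH_BUDGET,
        "elevated": elevated,
        "reason": ("per-locus override above the global default"
                   if elevated else "within the global default"),
    }


# ---------------------------------------------------------------------------
# Serialisation (YAML schema, versioned)
# ---------------------------------------------------------------------------

def _block_to_dict(b: MotifBlock) -> dict:
    return {"motif": b.motif, "min": b.min_count, "max": b.max_count, "ce": b.ce_role}


def _block_from_dict(d: dict, locus: str) -> MotifBlock:
    try:
        return MotifBlock(d["motif"], int(d.get("min", 0)), int(d.get("max", 30)),
                          d.get("ce", "unit"))
    except KeyError as e:
        raise PanelError(f"locus {locus}: structure block missing field {e}") from e


_STR_REQUIRED = ("name", "chromosome", "ref_start", "ref_end",
                 "upstream_flank", "downstream_flank", "structure",
                 "canonical_motif_len", "ploidy_class")
_SNP_REQUIRED = ("name", "chromosome", "position", "upstream_flank",
                 "downstream_flank", "ref_allele", "alt_allele", "category")


def save_panel(panel: PanelConfig, path) -> None:
    doc = {
        "panel": panel.name,
        "version": panel.version,
        "thresholds": {k: getattr(panel.thresholds, k)
                       for k in ThresholdSet.__dataclass_fields__},
        "str_loci": [],
        "snp_loci": [],
    }
    for l in panel.str_loci:
        d = {
            "name": l.name, "chromosome": l.chromosome,
            "ref_start": l.ref_start, "ref_end": l.ref_end,
            "upstream_flank": l.upstream_flank,
            "downstream_flank": l.downstream_flank,
            "structure": [_block_to_dict(b) for b in l.structure],
            "canonical_motif_len": l.canonical_motif_len,
            "ploidy_class": l.ploidy_class,
            "max_flank_mismatches": l.max_flank_mismatches,
            "n_amplicons": l.n_amplicons,
            "stutter_threshold_n1": l.stutter_threshold_n1,
        }
        if l.stutter_threshold_n2 is not None:
            d["stutter_threshold_n2"] = l.stutter_threshold_n2
        if l.stutter_threshold_np1 is not None:
            d["stutter_threshold_np1"] = l.stutter_threshold_np1
        doc["str_loci"].append(d)
    for s in panel.snp_loci:
        doc["snp_loci"].append({
            "name": s.name, "chromosome": s.chromosome, "position": s.position,
            "upstream_flank": s.upstream_flank,
            "downstream_flank": s.downstream_flank,
            "ref_allele": s.ref_allele, "alt_allele": s.alt_allele,
            "category": s.category,
            "max_flank_mismatches": s.max_flank_mismatches,
        })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_panel(path) -> PanelConfig:
    """Load and validate a panel configuration file.

    Threshold fields omitted from the file take their documented defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise PanelError(f"{path}: not a panel configuration file")
    thr = ThresholdSet(**(doc.get("thresholds") or {}))
    str_loci = []
    for d in doc.get("str_loci") or []:
        missing = [k for k in _STR_REQUIRED if k not in d]
        if missing:
            raise PanelError(
                f"STR locus {d.get('name', '<unnamed>')}: missing field(s) {missing}")
        str_loci.append(StrLocusDef(
            name=d["name"], chromosome=d["chromosome"],
            ref_start=int(d["ref_start"]), ref_end=int(d["ref_end"]),
            upstream_flank=d["upstream_flank"],
            downstream_flank=d["downstream_flank"],
            structure=tuple(_block_from_dict(b, d["name"]) for b in d["structure"]),
            canonical_motif_len=int(d["canonical_motif_len"]),
            ploidy_class=d["ploidy_class"],
            max_flank_mismatches=int(d.get("max_flank_mismatches",
                                           DEFAULT_FLANK_MISMATCH_BUDGET)),
            n_amplicons=int(d.get("n_amplicons", 1)),
            stutter_threshold_n1=float(d.get("stutter_threshold_n1", 0.15)),
            stutter_threshold_n2=d.get("stutter_threshold_n2"),
            stutter_threshold_np1=d.get("stutter_threshold_np1"),
        ))
    snp_loci = []
    for d in doc.get("snp_loci") or []:
        missing = [k for k in _SNP_REQUIRED if k not in d]
        if missing:
            raise PanelError(
                f"SNP locus {d.get('name', '<unnamed>')}: missing field(s) {missing}")
        snp_loci.append(SnpLocusDef(
            name=d["name"], chromosome=d["chromosome"], position=int(d["position"]),
            upstream_flank=d["upstream_flank"],
            downstream_flank=d["downstream_flank"],
            ref_allele=d["ref_allele"], alt_allele=d["alt_allele"],
            category=d["category"],
            max_flank_mismatches=int(d.get("max_flank_mismatches",
                                           DEFAULT_FLANK_MISMATCH_BUDGET)),
        ))
    return PanelConfig(name=doc.get("panel", "unnamed"), str_loci=str_loci,
                       snp_loci=snp_loci, thresholds=thr,
                       version=str(doc.get("version", "1")))


# ---------------------------------------------------------------------------
# Default bundled panel
# ---------------------------------------------------------------------------

def _locus_rng(name: str) -> np.random.Generator:
    # deterministic per-locus stream so the bundled panel is stable
    return np.random.default_rng(zlib.crc32(("amplistr:" + name).encode()))


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# (median read depth, n-1 stutter filter threshold %) per locus; depth
# medians double as the simulator's default per-locus means.  The DYS438
# median is kept at 5747 reads: the value is recorded inconsistently at
# its source and 5747 fits the locus's rank among its neighbours.
_AUTOSOMAL: dict[str, tuple[int, float]] = {
    "D3S1358": (18164, 15.0), "D20S482": (7353, 15.0), "TH01": (7332, 10.0),
    "D2S1338": (6180, 20.0), "D2S441": (5442, 7.5), "D8S1179": (5202, 25.0),
    "D18S51": (5043, 22.0), "D6S1043": (4939, 12.5), "D10S1248": (4837, 20.0),
    "D16S539": (4804, 20.0), "D4S2408": (4261, 7.5), "FGA": (4023, 25.0),
    "D22S1045": (3812, 20.0), "D17S1301": (3296, 20.0), "D12S391": (2871, 33.0),
    "TPOX": (2714, 10.0), "D21S11": (2602, 10.0), "D13S317": (2536, 12.5),
    "D9S1122": (2040, 12.5), "CSF1PO": (1912, 10.0), "PentaD": (1606, 7.5),
    "D19S433": (1572, 12.5), "D7S820": (1571, 10.0), "D1S1656": (1174, 25.0),
    "PentaE": (1158, 10.0), "vWA": (737, 22.0), "D5S818": (560, 12.5),
}
_X_STR: dict[str, tuple[int, float]] = {
    "DXS7132": (7540, 22.0), "HPRTB": (6803, 15.0), "DXS7423": (6440, 15.0),
    "DXS10074": (6214, 25.0), "DXS8378": (3852, 15.0), "DXS10135": (2610, 22.0),
    "DXS10103": (52, 22.0),
}
_Y_STR: dict[str, tuple[int, float]] = {
    "DYS389I": (10319, 20.0), "DYS438": (5747, 15.0), "DYS576": (5097, 15.0),
    "DYS390": (4765, 15.0), "DYS505": (3611, 15.0), "DYS570": (3411, 22.0),
    "DYS448": (3339, 15.0), "DYS612": (2903, 35.0), "DYS385a/b": (2807, 20.0),
    "DYS391": (2781, 20.0), "DYS549": (2666, 22.0), "DYS643": (2544, 20.0),
    "DYS533": (2189, 15.0), "DYS392": (2119, 30.0), "DYS439": (2091, 15.0),
    "DYS437": (2081, 45.0), "DYS19": (1819, 15.0), "DYF387S1": (1770, 20.0),
    "DYS635": (1539, 15.0), "DYS460": (1325, 15.0), "DYS389II": (1218, 35.0),
    "DYS481": (855, 50.0), "Y-GATA-H4": (727, 35.0), "DYS522": (498, 15.0),
}

# generic repeat motifs for loci without a printed structure
_TRI_LOCI = {"DYS481", "DYS612", "D22S1045", "DYS392"}
_PENTA_LOCI = {"PentaD", "PentaE", "DYS438", "DYS643"}
_HEXA_LOCI = {"DYS448"}
_TRI_MOTIFS = {"DYS481": "CTT", "DYS612": "CCT", "D22S1045": "ATT", "DYS392": "TAT"}
_PENTA_MOTIFS = {"PentaD": "AAAGA", "PentaE": "TCTTT", "DYS438": "TTTTC",
                 "DYS643": "CTTTT"}

# loci whose flanks need a higher mismatch budget
_ELEVATED_BUDGET = {"D1S1656": 5, "D19S433": 5, "HPRTB": 5, "DYS522": 5}

# printed bracketed structures, encoded exactly; block count bounds are
# this panel's allele ranges (long-block maxima are kept where the
# locus's stutter filter still exceeds the expected stutter ratio)
_PRINTED_STRUCTURES: dict[str, tuple[MotifBlock, ...]] = {
    "D21S11": (
        MotifBlock("TCTA", 2, 9), MotifBlock("TCTG", 3, 7), MotifBlock("TCTA", 1, 4),
        MotifBlock("TA", 0, 1, "none"), MotifBlock("TCTA", 1, 4),
        MotifBlock("TCA", 0, 1, "none"), MotifBlock("TCTA", 1, 3),
        MotifBlock("TCCATA", 0, 1, "none"), MotifBlock("TCTA", 3, 11),
    ),
    "D12S391": (MotifBlock("AGAT", 7, 16), MotifBlock("AGAC", 5, 12)),
    "D1S1656": (MotifBlock("TCTA", 0, 8), MotifBlock("TGA", 0, 1, "partial"),
                MotifBlock("TCTA", 4, 16)),
    "D19S433": (MotifBlock("AAGG", 0, 3), MotifBlock("TAGG", 0, 1),
                MotifBlock("AAGG", 4, 10), MotifBlock("AG", 0, 1, "partial")),
    "D2S1338": (MotifBlock("TGCC", 3, 8), MotifBlock("GTCC", 0, 1),
                MotifBlock("TTCC", 4, 16)),
    "D18S51": (MotifBlock("AGAA", 6, 15),),
    "PentaD": (MotifBlock("AAAGA", 2, 13),),
    "DXS10135": (MotifBlock("AAGA", 1, 5), MotifBlock("GAAAGGA", 0, 1, "none"),
                 MotifBlock("AAGA", 5, 18), MotifBlock("AAAG", 0, 1)),
}

#: stutter-rate slopes per motif length assumed when sizing generic
#: allele ranges (ratio increase per uninterrupted unit above the floor);
#: mirrors the simulator's defaults so that typical stutter stays below
#: each locus's filter threshold, as vendor thresholds are set in practice
_RANGE_SLOPES = {3: 0.03, 4: 0.012, 5: 0.005, 6: 0.0}
_RANGE_FLOOR = 4
_RANGE_HEADROOM = 0.6  # target max stutter ratio as a fraction of the filter

# GRCh37 anchors for the loci with printed coordinates; everything else is
# assigned a stable placeholder range far from real annotation.
_PRINTED_COORDS = {
    "PentaD": ("chr21", 45056086, 45056150),
    "DXS10135": ("chrX", 9306342, 9306440),
}

_DUAL_AMPLICON = {"DYS385a/b", "DYF387S1"}

# SNPs named in the evaluation (problem loci and outliers); the remaining
# panel members are synthetic placeholder identifiers.
_NAMED_HID = ["rs1736442", "rs2920816", "rs1031825", "rs7041158", "rs907100",
              "rs1493232", "rs1294331", "rs1454361", "rs338882", "rs6955448",
              "rs4530059", "rs1979255", "rs917115", "rs10488710", "rs354439",
              "rs279844"]
_NAMED_AIM = ["rs798443"]
_NAMED_PHENO = ["rs1229984"]

#: default simulator depth means for the named SNPs (reads)
SNP_DEPTH_OVERRIDES = {"rs1736442": 60, "rs2920816": 72, "rs1031825": 80,
                       "rs7041158": 90, "rs917115": 1212}


def _range_for(motif_len: int, threshold: float) -> tuple[int, int]:
    """Allele unit range for a generic locus, sized so the expected n-1
    stutter ratio at the longest allele stays below the locus filter."""
    slope = _RANGE_SLOPES.get(motif_len, 0.0)
    if slope <= 0:
        return 8, 16
    max_units = int(_RANGE_FLOOR + _RANGE_HEADROOM * threshold / slope)
    max_units = max(6, min(24, max_units))
    return max(3, max_units - 7), max_units


def _default_structure(name: str,
                       threshold: float) -> tuple[tuple[MotifBlock, ...], int]:
    if name in _PRINTED_STRUCTURES:
        st = _PRINTED_STRUCTURES[name]
        motif_len = max(len(b.motif) for b in st if b.ce_role == "unit")
        if name == "D21S11":
            motif_len = 4
        return st, motif_len
    if name in _TRI_LOCI:
        lo, hi = _range_for(3, threshold)
        return (MotifBlock(_TRI_MOTIFS[name], lo, hi),), 3
    if name in _PENTA_LOCI:
        lo, hi = _range_for(5, threshold)
        return (MotifBlock(_PENTA_MOTIFS[name], lo, hi),), 5
    if name in _HEXA_LOCI:
        return (MotifBlock("AGAGAT", 8, 16),), 6
    rng = _locus_rng(name + ":motif")
    motif = "".join(rng.choice(list("ACGT"), size=4))
    # avoid homopolymer or dimer-periodic motifs, which make parsing ambiguous
    while len(set(motif)) < 3 or motif[:2] == motif[2:]:
        motif = "".join(rng.choice(list("ACGT"), size=4))
    lo, hi = _range_for(4, threshold)
    return (MotifBlock(motif, lo, hi),), 4


def _chromosome_for(name: str, ploidy: str) -> str:
    if ploidy == "X":
        return "chrX"
    if ploidy == "Y":
        return "chrY"
    special = {"CSF1PO": "chr5", "FGA": "chr4", "TH01": "chr11", "TPOX": "chr2",
               "vWA": "chr12", "PentaD": "chr21", "PentaE": "chr15"}
    if name in special:
        return special[name]
    digits = ""
    for ch in name[1:]:
        if ch.isdigit():
            digits += ch
        else:
            break
    return f"chr{digits or '1'}"


def _build_str_locus(name: str, ploidy: str, idx: int,
                     stutter_threshold_pct: float) -> StrLocusDef:
    structure, motif_len = _default_structure(name, stutter_threshold_pct / 100.0)
    rng = _locus_rng(name)
    up = _random_flank(rng, 20)
    down = _random_flank(rng, 20)
    if name in _PRINTED_COORDS:
        chrom, start, end = _PRINTED_COORDS[name]
    else:
        chrom = _chromosome_for(name, ploidy)
        start = 10_000_000 + idx * 100_000
        max_len = sum(b.max_count * len(b.motif) for b in structure)
        end = start + max_len - 1
    return StrLocusDef(
        name=name, chromosome=chrom, ref_start=start, ref_end=end,
        upstream_flank=up, downstream_flank=down, structure=structure,
        canonical_motif_len=motif_len, ploidy_class=ploidy,
        max_flank_mismatches=_ELEVATED_BUDGET.get(name,
                                                  DEFAULT_FLANK_MISMATCH_BUDGET),
        n_amplicons=2 if name in _DUAL_AMPLICON else 1,
        stutter_threshold_n1=stutter_threshold_pct / 100.0,
    )


def _build_snp_locus(name: str, category: str, idx: int) -> SnpLocusDef:
    rng = _locus_rng(name)
    up = _random_flank(rng, 20)
    down = _random_flank(rng, 20)
    ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
    chrom = f"chr{1 + idx % 22}"
    return SnpLocusDef(name=name, chromosome=chrom,
                       position=50_000_000 + idx * 10_000,
                       upstream_flank=up, downstream_flank=down,
                       ref_allele=str(ref), alt_allele=str(alt),
                       category=category)


def default_panel(include_aim_phenotype: bool = True) -> PanelConfig:
    """The bundled 58-STR / 94-HID-SNP default panel.

    Census: 27 autosomal, 7 X and 24 Y STRs; 94 HID SNPs, and optionally
    56 AIM and 24 phenotype SNPs.  Repeat structures printed in the
    evaluation literature are encoded exactly; other loci carry realistic
    placeholder structures and synthetic flanks.
    """
    str_loci: list[StrLocusDef] = []
    idx = 0
    for table, ploidy in ((_AUTOSOMAL, "autosomal"), (_X_STR, "X"), (_Y_STR, "Y")):
        for name, (_depth, thr) in table.items():
            str_loci.append(_build_str_locus(name, ploidy, idx, thr))
            idx += 1
    snp_loci: list[SnpLocusDef] = []
    sidx = 0
    hid_names = list(_NAMED_HID) + [f"rs9{1000000 + i}" for i in
                                    range(94 - len(_NAMED_HID))]
    for n in hid_names:
        snp_loci.append(_build_snp_locus(n, "HID", sidx)); sidx += 1
    if include_aim_phenotype:
        aim_names = list(_NAMED_AIM) + [f"rs8{2000000 + i}" for i in
                                        range(56 - len(_NAMED_AIM))]
        pheno_names = list(_NAMED_PHENO) + [f"rs7{3000000 + i}" for i in
                                            range(24 - len(_NAMED_PHENO))]
        for n in aim_names:
            snp_loci.append(_build_snp_locus(n, "AIM", sidx)); sidx += 1
        for n in pheno_names:
            snp_loci.append(_build_snp_locus(n, "phenotype", sidx)); sidx += 1
    return PanelConfig(name="amplistr-default", str_loci=str_loci,
                       snp_loci=snp_loci)


def default_depth_means() -> dict[str, float]:
    """Per-locus default mean read depths for the simulator (reads)."""
    means: dict[str, float] = {}
    for table in (_AUTOSOMAL, _X_STR, _Y_STR):
        for name, (depth, _thr) in table.items():
            means[name] = float(depth)
    # SNP names are deterministic; regenerate them cheaply
    hid_names = list(_NAMED_HID) + [f"rs9{1000000 + i}" for i in
                                    range(94 - len(_NAMED_HID))]
    aim_names = list(_NAMED_AIM) + [f"rs8{2000000 + i}" for i in range(55)]
    pheno_names = list(_NAMED_PHENO) + [f"rs7{3000000 + i}" for i in range(23)]
    for n in hid_names + aim_names + pheno_names:
        if n in SNP_DEPTH_OVERRIDES:
            means[n] = float(SNP_DEPTH_OVERRIDES[n])
        else:
            rng = _locus_rng(n + ":depth")
            means[n] = float(rng.integers(200, 900))
    return means
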