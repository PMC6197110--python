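import numpy as np
import pytest

from amplistr.panel import (MotifBlock, PanelConfig, SnpLocusDef, StrLocusDef,
                            default_panel)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_str_locus(name="TOY1", motif="AGAT", lo=3, hi=15, up="ACGTACGTACGTACGTACGT",
                   down="TGCATGCATGCATGCATGCA", **kw):
    defaults = dict(
        name=name, chromosome="chr1", ref_start=1_000_000,
        ref_end=1_000_000 + hi * len(motif) - 1,
        upstream_flank=up, downstream_flank=down,
        structure=(MotifBlock(motif, lo, hi),),
        canonical_motif_len=len(motif), ploidy_class="autosomal",
    )
    defaults.update(kw)
    return StrLocusDef(**defaults)


def make_snp_locus(name="rsTOY", up="GGATCCGGATCCGGATCCAA",
                   down="CCTAGGCCTAGGCCTAGGTT", ref="A", alt="G", **kw):
    defaults = dict(name=name, chromosome="chr2", position=2_000_000,
                    upstream_flank=up, downstream_flank=down,
                    ref_allele=ref, alt_allele=alt, category="HID")
    defaults.update(kw)
    return SnpLocusDef(**defaults)


@pytest.fixture()
def toy_panel():
    return PanelConfig(name="toy", str_loci=[make_str_locus()],
                       snp_loci=[make_snp_locus()])
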