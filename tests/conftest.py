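import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from msquant.panel import MicrosatelliteLocus, Panel
from msquant.refrecon import ReferenceWindow
from msquant.sam_model import AlignedRead


@pytest.fixture
def locus_a11() -> MicrosatelliteLocus:
    """A(11) tract at chrT:[100, 110]."""
    return MicrosatelliteLocus(
        locus_id="TESTG_1", gene="TESTG", chrom="chrT", start=100, end=110,
        repeat_unit="A",
    )


@pytest.fixture
def ref_a11() -> ReferenceWindow:
    """Reference context around the A(11) tract: positions 90-120."""
    return ReferenceWindow(
        chrom="chrT", start=90, seq="CGTCGGATCG" + "A" * 11 + "GTCCGATGGC"
    )


@pytest.fixture
def small_panel(locus_a11) -> Panel:
    other = MicrosatelliteLocus(
        locus_id="OTHG_1", gene="OTHG", chrom="chrU", start=200, end=212,
        repeat_unit="T",
    )
    return Panel(loci=(locus_a11, other), name="test2")


def make_plain_read(
    qname="r", flag=0, rname="chrT", pos=90, mapq=60,
    cigar=(("M", 31),), seq=None, md=None, nm=None,
):
    if seq is None:
        n = sum(l for op, l in cigar if op in "MIS=X")
        seq = "A" * n
    return AlignedRead(
        qname=qname, flag=flag, rname=rname, pos=pos, mapq=mapq,
        cigar=tuple(cigar), seq=seq, md=md, nm=nm,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
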