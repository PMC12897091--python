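"""Reference reconstruction from CIGAR strings and MD tags.

Aligned files document only differences relative to the reference genome;
the reference itself is recovered per read by walking the CIGAR and MD tag
jointly, then per locus by preferring a mutation-free "reference read" and
falling back to a per-position majority consensus of reconstructions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .panel import MicrosatelliteLocus, reads_for_locus
from .sam_model import AlignedRead, reference_length

__all__ = [
    "MdToken",
    "MdParseError",
    "ReconstructionError",
    "NoReferenceError",
    "ReferenceWindow",
    "LocusReference",
    "Provenance",
    "parse_md",
    "is_reference_read",
    "reconstruct_reference",
    "build_locus_reference",
]

logger = logging.getLogger(__name__)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class MdParseError(ValueError):
    """MD grammar violation; message carries the string offset."""


class ReconstructionError(ValueError):
    """CIGAR/MD inconsistency detected during the joint walk."""


class NoReferenceError(ValueError):
    """No covering read from which to establish a locus reference."""


@dataclass(frozen=True)
class MdToken:
    """One token of an MD tag: a match run, a mismatch base, or deleted bases."""

    kind: str  # match_run | mismatch_base | deletion_bases
    length: int = 0
    bases: str = ""

    def __post_init__(self) -> None:
        if self.kind == "match_run" and self.length < 0:
            raise ValueError("match_run length must be >= 0")
        if self.kind == "mismatch_base" and len(self.bases) != 1:
            raise ValueError("mismatch_base carries exactly one base")
        if self.kind == "deletion_bases" and not self.bases:
            raise ValueError("deletion_bases must be non-empty")


@dataclass(frozen=True)
class ReferenceWindow:
    """A reconstructed stretch of reference sequence (1-based start)."""

    chrom: str
    start: int
    seq: str

    @property
    def end(self) -> int:
        """1-based inclusive last coordinate."""
        return self.start + len(self.seq) - 1

    def slice(self, start: int, end: int) -> "ReferenceWindow":
        """Restrict to the 1-based inclusive interval [start, end]."""
        if start < self.start or end > self.end:
            raise ValueError(
                f"[{start}, {end}] outside window [{self.start}, {self.end}]"
            )
        off = start - self.start
        return ReferenceWindow(self.chrom, start, self.seq[off : off + end - start + 1])


class Provenance(str, Enum):
    DIRECT = "direct"
    RECONSTRUCTED_CONSENSUS = "reconstructed_consensus"


@dataclass(frozen=True)
class LocusReference:
    """Reference established for one locus window, with provenance."""

    window: ReferenceWindow
    provenance: Provenance
    n_support: int
    n_ambiguous: int = 0


def parse_md(md: str) -> list[MdToken]:
    """Parse an MD tag into tokens, enforcing the alternating grammar
    ``NUMBER ((BASE | '^'BASES) NUMBER)*``.

    Zero-length match runs are preserved (e.g. ``"0A5"`` starts with a
    mismatch immediately).
    """
    tokens: list[MdToken] = []
    pos = 0
    expect_number = True
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise MdParseError(f"invalid MD character at offset {pos} in {md!r}")
        num, deletion, base = m.groups()
        if num is not None:
            if not expect_number:
                raise MdParseError(
                    f"unexpected number at offset {m.start()} in {md!r}"
                )
            tokens.append(MdToken("match_run", length=int(num)))
            expect_number = False
        elif deletion is not None:
            if expect_number:
                raise MdParseError(
                    f"MD must start with a match run length (offset {m.start()} in {md!r})"
                )
            tokens.append(MdToken("deletion_bases", bases=deletion[1:].upper()))
            expect_number = True
        else:
            if expect_number:
                raise MdParseError(
                    f"MD must start with a match run length (offset {m.start()} in {md!r})"
                )
            tokens.append(MdToken("mismatch_base", bases=base.upper()))
            expect_number = True
        pos = m.end()
    if pos != len(md):
        raise MdParseError(f"invalid MD character at offset {pos} in {md!r}")
    if expect_number:
        raise MdParseError(f"MD tag {md!r} must end with a match run length")
    return tokens


class MdCursor:
    """Consumable view over MD tokens, synchronised with a CIGAR walk.

    ``take_match`` yields the reference base at a mismatch (or None on match);
    ``take_deletion`` returns the deleted reference bases for a D run.
    """

    def __init__(self, tokens: Sequence[MdToken], source: str = "") -> None:
        self._tokens = list(tokens)
        self._i = 0
        self._offset = 0  # position inside the current match run / deletion bases
        self._source = source

    def _current(self) -> MdToken | None:
        # skip exhausted zero-remainder match runs
        while self._i < len(self._tokens):
            tok = self._tokens[self._i]
            if tok.kind == "match_run" and tok.length - self._offset == 0:
                self._i += 1
                self._offset = 0
                continue
            return tok
        return None

    def take_match(self) -> str | None:
        """Consume one aligned (M/=/X) reference position; return the
        reference base if it is an MD mismatch, else None."""
        tok = self._current()
        if tok is None:
            raise ReconstructionError(
                f"MD tag {self._source!r} exhausted before CIGAR match run"
            )
        if tok.kind == "match_run":
            self._offset += 1
            return None
        if tok.kind == "mismatch_base":
            self._i += 1
            self._offset = 0
            return tok.bases
        raise ReconstructionError(
            f"MD tag {self._source!r} has a deletion where CIGAR expects a match"
        )

    def take_deletion(self, length: int) -> str:
        """Consume ``length`` deleted reference bases (CIGAR D run)."""
        tok = self._current()
        if tok is None or tok.kind != "deletion_bases":
            raise ReconstructionError(
                f"MD tag {self._source!r} lacks deletion bases for CIGAR D run"
            )
        bases = tok.bases[self._offset : self._offset + length]
        if len(bases) < length:
            raise ReconstructionError(
                f"MD deletion in {self._source!r} shorter than CIGAR D run"
            )
        self._offset += length
        if self._offset == len(tok.bases):
            self._i += 1
            self._offset = 0
        return bases

    def finish(self) -> None:
        """Assert the MD tag is fully consumed."""
        if self._current() is not None:
            raise ReconstructionError(
                f"MD tag {self._source!r} has leftover tokens after CIGAR walk"
            )


def is_reference_read(read: AlignedRead) -> bool:
    """True iff the read is identical to the reference over its aligned span.

    Requires an MD tag free of mismatch/deletion tokens *and* a CIGAR free of
    I/D/X operations (soft/hard clips at the ends are permitted — clipped
    bases are not part of the alignment). With no MD tag the CIGAR decides
    alone; with neither, the read cannot be classified and is not a reference.
    """
    has_cigar = bool(read.cigar)
    if not has_cigar and read.md is None:
        logger.warning("read %s has neither CIGAR nor MD; not a reference", read.qname)
        return False
    if has_cigar:
        for op, _ in read.cigar:
            if op in "IDX":
                return False
    if read.md is not None:
        for tok in parse_md(read.md):
            if tok.kind != "match_run":
                return False
    return has_cigar


def reconstruct_reference(read: AlignedRead) -> ReferenceWindow:
    """Rebuild the reference sequence under a read's alignment.

    Joint CIGAR/MD walk: soft-clipped and inserted bases are dropped, M-run
    bases are copied from the read but overwritten with the MD mismatch base
    (the reference base), and deleted bases are restored from MD ``^`` tokens.
    The result spans exactly the reference-consumed length starting at
    ``read.pos``.
    """
    if not read.cigar:
        raise ReconstructionError(f"read {read.qname}: no CIGAR to reconstruct from")
    if read.md is None:
        raise ReconstructionError(f"read {read.qname}: no MD tag to reconstruct from")
    if read.seq is None:
        raise ReconstructionError(f"read {read.qname}: no SEQ to reconstruct from")
    cursor = MdCursor(parse_md(read.md), source=read.md)
    ref: list[str] = []
    qi = 0
    for op, length in read.cigar:
        if op in "M=X":
            for _ in range(length):
                mismatch = cursor.take_match()
                ref.append(mismatch if mismatch is not None else read.seq[qi])
                qi += 1
        elif op == "I" or op == "S":
            qi += length  # inserted/clipped bases are not reference
        elif op == "D":
            ref.append(cursor.take_deletion(length))
        elif op == "N":
            # skipped region: reference-consuming gap; amplicon data should not
            # contain these, fill with N and flag
            logger.warning("read %s: N operation treated as unknown gap", read.qname)
            ref.append("N" * length)
        elif op == "H" or op == "P":
            continue
        else:  # pragma: no cover - CIGAR_OPS already constrains this
            raise ReconstructionError(f"unsupported CIGAR op {op!r}")
    cursor.finish()
    seq = "".join(ref)
    expected = reference_length(read.cigar)
    if len(seq) != expected:
        raise ReconstructionError(
            f"read {read.qname}: reconstructed {len(seq)} bases, "
            f"CIGAR {read.cigar} consumes {expected} (MD {read.md!r})"
        )
    return ReferenceWindow(chrom=read.rname, start=read.pos, seq=seq)


def build_locus_reference(
    reads: Iterable[AlignedRead],
    locus: MicrosatelliteLocus,
    flank: int = 1,
) -> LocusReference:
    """Establish the reference sequence over ``[start - flank, end + flank]``.

    If at least one mutation-free reference read covers the window, its
    (trivially reconstructed) sequence is used directly. Otherwise every
    covering read is reconstructed and a per-position majority consensus is
    taken; ties go to the base supported by the highest-MAPQ read, then
    lexicographically.
    """
    wstart, wend = locus.start - flank, locus.end + flank
    covering = reads_for_locus(reads, locus, flank)
    if not covering:
        raise NoReferenceError(
            f"locus {locus.locus_id}: no covering reads to establish a reference"
        )
    ref_reads = [r for r in covering if r.md is not None and is_reference_read(r)]
    if ref_reads:
        best = max(ref_reads, key=lambda r: r.mapq)
        window = reconstruct_reference(best).slice(wstart, wend)
        return LocusReference(
            window=window,
            provenance=Provenance.DIRECT,
            n_support=len(ref_reads),
        )
    usable = [r for r in covering if r.md is not None]
    if not usable:
        raise NoReferenceError(
            f"locus {locus.locus_id}: covering reads carry no MD tags"
        )
    slices = [(reconstruct_reference(r).slice(wstart, wend), r.mapq) for r in usable]
    n = wend - wstart + 1
    consensus: list[str] = []
    n_ambiguous = 0
    for i in range(n):
        votes: dict[str, int] = {}
        best_mapq: dict[str, int] = {}
        for window, mapq in slices:
            base = window.seq[i]
            votes[base] = votes.get(base, 0) + 1
            best_mapq[base] = max(best_mapq.get(base, -1), mapq)
        if len(votes) > 1:
            n_ambiguous += 1
        consensus.append(
            max(votes, key=lambda b: (votes[b], best_mapq[b], -ord(b)))
        )
    return LocusReference(
        window=ReferenceWindow(locus.chrom, wstart, "".join(consensus)),
        provenance=Provenance.RECONSTRUCTED_CONSENSUS,
        n_support=len(usable),
        n_ambiguous=n_ambiguous,
    )
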