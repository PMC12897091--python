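"""Aligned-read model: SAM record parsing, FLAG decoding, and read validity filters.

The text-mode SAM parser is implemented natively so the downstream algorithm
is testable without binary fixtures; BAM input is handled at the pipeline
boundary by an htslib-compatible reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AlignedRead",
    "ReadFilterPolicy",
    "SamParseError",
    "FLAG_BITS",
    "CIGAR_OPS",
    "QUERY_CONSUMING",
    "REF_CONSUMING",
    "parse_sam_record",
    "decode_flag",
    "encode_flag",
    "passes_filters",
    "filter_reads",
    "query_length",
    "reference_length",
]

#: Valid CIGAR operation codes.
CIGAR_OPS = frozenset("MIDNSHP=X")

#: CIGAR operations that consume query (read) bases.
QUERY_CONSUMING = frozenset("MIS=X")

#: CIGAR operations that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")

#: SAM FLAG bit semantics (subset relevant to single-end amplicon analysis,
#: plus the standard pairing bits so decoding round-trips).
FLAG_BITS: dict[str, int] = {
    "paired": 0x1,
    "proper_pair": 0x2,
    "unmapped": 0x4,
    "mate_unmapped": 0x8,
    "reverse": 0x10,
    "mate_reverse": 0x20,
    "first_in_pair": 0x40,
    "second_in_pair": 0x80,
    "secondary": 0x100,
    "qc_fail": 0x200,
    "duplicate": 0x400,
    "supplementary": 0x800,
}

_FLAG_NAMES = {bit: name for name, bit in FLAG_BITS.items()}

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


class SamParseError(ValueError):
    """Raised when a SAM record line cannot be parsed; names the offending field."""


@dataclass(frozen=True)
class AlignedRead:
    """One aligned SAM record (mandatory fields plus the MD/NM tags).

    Coordinates follow the SAM convention: ``pos`` is the 1-based leftmost
    reference coordinate of the alignment.
    """

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    seq: str | None
    md: str | None = None
    nm: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SamParseError(f"POS must be >= 1, got {self.pos}")
        if not 0 <= self.mapq <= 255:
            raise SamParseError(f"MAPQ must be in [0, 255], got {self.mapq}")
        for op, length in self.cigar:
            if op not in CIGAR_OPS:
                raise SamParseError(f"invalid CIGAR operation {op!r}")
            if length < 1:
                raise SamParseError(f"CIGAR run length must be >= 1, got {length}{op}")
        self._check_clip_placement()
        if self.seq is not None and self.cigar:
            qlen = query_length(self.cigar)
            if qlen != len(self.seq):
                raise SamParseError(
                    f"CIGAR consumes {qlen} query bases but SEQ has {len(self.seq)}"
                )
        if self.nm is not None and self.nm < 0:
            raise SamParseError(f"NM must be >= 0, got {self.nm}")

    def _check_clip_placement(self) -> None:
        # H only at the outermost ends; S inside H but outside everything else.
        ops = [op for op, _ in self.cigar]
        core = ops[:]
        for end in (0, -1):
            if core and core[end] == "H":
                core.pop(end)
        if "H" in core:
            raise SamParseError("H operations allowed only at CIGAR ends")
        for end in (0, -1):
            if core and core[end] == "S":
                core.pop(end)
        if "S" in core:
            raise SamParseError("S operations allowed only at CIGAR ends (inside H)")

    @property
    def reference_span(self) -> tuple[int, int]:
        """1-based inclusive [start, end] reference interval covered by the alignment."""
        return self.pos, self.pos + reference_length(self.cigar) - 1

    def has_flag(self, mask: int) -> bool:
        return bool(self.flag & mask)


def query_length(cigar: Sequence[tuple[str, int]]) -> int:
    """Number of query (SEQ) bases consumed by a CIGAR."""
    return sum(n for op, n in cigar if op in QUERY_CONSUMING)


def reference_length(cigar: Sequence[tuple[str, int]]) -> int:
    """Number of reference bases consumed by a CIGAR."""
    return sum(n for op, n in cigar if op in REF_CONSUMING)


def _parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    if text == "*":
        return ()
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise SamParseError(f"invalid CIGAR token at offset {pos} in {text!r}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise SamParseError(f"invalid CIGAR token at offset {pos} in {text!r}")
    return tuple(ops)


def _int_field(value: str, name: str) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise SamParseError(f"non-integer {name} field: {value!r}") from exc


def parse_sam_record(line: str) -> AlignedRead:
    """Parse one tab-delimited SAM record line into an :class:`AlignedRead`.

    Optional fields other than ``MD:Z`` and ``NM:i`` are ignored. A CIGAR of
    ``*`` yields an empty operation list; a SEQ of ``*`` yields ``seq=None``.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise SamParseError(
            f"SAM record has {len(fields)} fields; 11 mandatory fields required"
        )
    md: str | None = None
    nm: int | None = None
    for tag in fields[11:]:
        if tag.startswith("MD:Z:"):
            md = tag[5:]
        elif tag.startswith("NM:i:"):
            nm = _int_field(tag[5:], "NM")
    seq = fields[9]
    return AlignedRead(
        qname=fields[0],
        flag=_int_field(fields[1], "FLAG"),
        rname=fields[2],
        pos=_int_field(fields[3], "POS"),
        mapq=_int_field(fields[4], "MAPQ"),
        cigar=_parse_cigar(fields[5]),
        seq=None if seq == "*" else seq,
        md=md,
        nm=nm,
    )


def decode_flag(flag: int) -> frozenset[str]:
    """Decode a FLAG bitfield into the set of alignment properties it encodes.

    Unknown high bits are ignored; ``encode_flag(decode_flag(f))`` reproduces
    the modeled bits of ``f``.
    """
    if flag < 0:
        raise ValueError(f"FLAG must be >= 0, got {flag}")
    return frozenset(name for name, bit in FLAG_BITS.items() if flag & bit)


def encode_flag(properties: Iterable[str]) -> int:
    """Inverse of :func:`decode_flag` on the modeled bit set."""
    flag = 0
    for name in properties:
        flag |= FLAG_BITS[name]
    return flag


@dataclass(frozen=True)
class ReadFilterPolicy:
    """Validity criteria for reads entering the analysis.

    Defaults follow the published filter set: MAPQ >= 60 and exclusion of
    unmapped (0x4), secondary (0x100) and supplementary (0x800) alignments.
    Duplicate (0x400) and QC-fail (0x200) reads are *not* excluded by default
    but may be added to ``forbidden_flags``.
    """

    min_mapq: int = 60
    forbidden_flags: frozenset[int] = frozenset({0x4, 0x100, 0x800})
    require_alignment: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_mapq <= 255:
            raise ValueError(f"min_mapq must be in [0, 255], got {self.min_mapq}")

    @property
    def forbidden_mask(self) -> int:
        mask = 0
        for bit in self.forbidden_flags:
            mask |= bit
        return mask


def passes_filters(read: AlignedRead, policy: ReadFilterPolicy | None = None) -> bool:
    """True iff the read satisfies every policy predicate.

    Reads with no CIGAR (``*``) or no SEQ carry no usable alignment and fail
    when ``policy.require_alignment`` is set.
    """
    if policy is None:
        policy = ReadFilterPolicy()
    if read.mapq < policy.min_mapq:
        return False
    if read.flag & policy.forbidden_mask:
        return False
    if policy.require_alignment and (not read.cigar or read.seq is None):
        return False
    return True


def filter_reads(
    reads: Iterable[AlignedRead], policy: ReadFilterPolicy | None = None
) -> list[AlignedRead]:
    """Retain only reads passing the policy; idempotent and contractive."""
    if policy is None:
        policy = ReadFilterPolicy()
    return [r for r in reads if passes_filters(r, policy)]
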