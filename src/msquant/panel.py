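"""Microsatellite panel definition and read-to-locus assignment.

Panel files are BED-dialect TSV (0-based half-open coordinates, '#' comments
allowed) with columns ``chrom  start  end  locus_id  gene  repeat_unit``.
Internally all coordinates are 1-based inclusive, matching SAM POS, so the
conversion happens exactly once at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .sam_model import AlignedRead, reference_length

__all__ = [
    "MicrosatelliteLocus",
    "Panel",
    "PanelFormatError",
    "load_panel",
    "write_panel",
    "reads_for_locus",
    "count_valid_reads",
]

logger = logging.getLogger(__name__)

_COLUMNS = ("chrom", "start", "end", "locus_id", "gene", "repeat_unit")

_VALID_BASES = frozenset("ACGTN")


class PanelFormatError(ValueError):
    """Raised for malformed panel files; carries the 1-based row number."""


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One microsatellite repeat tract (1-based inclusive coordinates)."""

    locus_id: str
    gene: str
    chrom: str
    start: int
    end: int
    repeat_unit: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.locus_id}: start ({self.start}) must be <= end ({self.end})"
            )
        if not self.repeat_unit:
            raise ValueError(f"{self.locus_id}: repeat_unit must be non-empty")
        if set(self.repeat_unit) - _VALID_BASES:
            raise ValueError(
                f"{self.locus_id}: repeat_unit {self.repeat_unit!r} has invalid bases"
            )
        if self.length < len(self.repeat_unit):
            raise ValueError(
                f"{self.locus_id}: tract shorter than one repeat unit"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Panel:
    """An ordered collection of microsatellite loci, sorted by (chrom, start)."""

    loci: tuple[MicrosatelliteLocus, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for locus in self.loci:
            if locus.locus_id in seen:
                raise PanelFormatError(f"duplicate locus_id {locus.locus_id!r}")
            seen.add(locus.locus_id)
        object.__setattr__(
            self, "loci", tuple(sorted(self.loci, key=lambda l: (l.chrom, l.start)))
        )

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def genes(self) -> tuple[str, ...]:
        """Distinct gene symbols in first-appearance order."""
        out: list[str] = []
        for locus in self.loci:
            if locus.gene not in out:
                out.append(locus.gene)
        return tuple(out)

    def by_gene(self) -> dict[str, tuple[MicrosatelliteLocus, ...]]:
        grouped: dict[str, list[MicrosatelliteLocus]] = {}
        for locus in self.loci:
            grouped.setdefault(locus.gene, []).append(locus)
        return {g: tuple(ls) for g, ls in grouped.items()}

    def get(self, locus_id: str) -> MicrosatelliteLocus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)


def load_panel(path: str | Path, name: str | None = None) -> Panel:
    """Load a BED-dialect TSV panel file.

    BED rows (0-based, half-open) are converted to 1-based inclusive
    coordinates: ``start_1 = start_bed + 1``, ``end_1 = end_bed``.
    """
    path = Path(path)
    loci: list[MicrosatelliteLocus] = []
    with path.open() as handle:
        for row_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(_COLUMNS):
                raise PanelFormatError(
                    f"{path}:{row_no}: expected {len(_COLUMNS)} columns "
                    f"({', '.join(_COLUMNS)}), got {len(fields)}"
                )
            chrom, start_s, end_s, locus_id, gene, unit = fields[:6]
            try:
                bed_start, bed_end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelFormatError(
                    f"{path}:{row_no}: non-integer coordinate"
                ) from exc
            if bed_start >= bed_end:
                raise PanelFormatError(
                    f"{path}:{row_no}: BED start ({bed_start}) must be < end ({bed_end})"
                )
            try:
                loci.append(
                    MicrosatelliteLocus(
                        locus_id=locus_id,
                        gene=gene,
                        chrom=chrom,
                        start=bed_start + 1,
                        end=bed_end,
                        repeat_unit=unit.upper(),
                    )
                )
            except ValueError as exc:
                raise PanelFormatError(f"{path}:{row_no}: {exc}") from exc
    if not loci:
        logger.warning("panel file %s contains no loci", path)
    try:
        return Panel(loci=tuple(loci), name=name or path.stem)
    except PanelFormatError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to BED-dialect TSV (inverse of :func:`load_panel`)."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("#" + "\t".join(_COLUMNS) + "\n")
        for locus in panel:
            handle.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.locus_id}\t{locus.gene}\t{locus.repeat_unit}\n"
            )


def reads_for_locus(
    reads: Iterable[AlignedRead], locus: MicrosatelliteLocus, flank: int = 1
) -> list[AlignedRead]:
    """Reads whose alignment fully covers the flanked locus interval.

    Full coverage (not mere overlap) is required: amplicon reads are designed
    to span whole loci, and partial reads would undercount repeat-internal
    events. The flank (default 1) makes insertions anchored immediately
    before the first repeat base observable.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    wstart, wend = locus.start - flank, locus.end + flank
    out: list[AlignedRead] = []
    for read in reads:
        if read.rname != locus.chrom or not read.cigar:
            continue
        span_start, span_end = read.reference_span
        if span_start <= wstart and span_end >= wend:
            out.append(read)
    return out


def count_valid_reads(
    reads: Iterable[AlignedRead], panel: Panel, flank: int = 1
) -> dict[str, int]:
    """Per-locus count of covering reads.

    A read covering several loci counts once per locus, so the total over loci
    may exceed the number of reads.
    """
    reads = list(reads)
    return {
        locus.locus_id: len(reads_for_locus(reads, locus, flank)) for locus in panel
    }
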