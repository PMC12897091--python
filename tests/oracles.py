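"""Independent oracles used by the test suite.

These deliberately re-derive expected values by different means than the
package (column-expansion walks, brute-force pair counting) so that the
implementation and its checks cannot share a bug.
"""

from __future__ import annotations

import re
from itertools import product

_MD_RE = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")


def expand_md(md: str) -> list[tuple[str, str]]:
    """Expand an MD tag into one symbol per reference position:
    ('=', '') for a match, ('X', refbase) for a mismatch,
    ('D', refbase) for a deleted base."""
    out: list[tuple[str, str]] = []
    for num, deletion, base in _MD_RE.findall(md):
        if num:
            out.extend([("=", "")] * int(num))
        elif deletion:
            out.extend(("D", b) for b in deletion[1:])
        else:
            out.append(("X", base))
    return out


def oracle_reconstruct(seq: str, cigar, md: str) -> str:
    """Reference sequence via column expansion (independent of MdCursor)."""
    cols = expand_md(md)
    ref: list[str] = []
    qi = 0
    ci = 0
    for op, length in cigar:
        if op in "M=X":
            for _ in range(length):
                sym, base = cols[ci]
                assert sym in "=X"
                ref.append(base if sym == "X" else seq[qi])
                qi += 1
                ci += 1
        elif op == "D":
            for _ in range(length):
                sym, base = cols[ci]
                assert sym == "D"
                ref.append(base)
                ci += 1
        elif op in "IS":
            qi += length
        elif op == "N":
            ref.append("N" * length)
    assert ci == len(cols)
    return "".join(ref)


def oracle_events(seq: str, cigar, md: str, pos: int) -> list[tuple]:
    """All (ref_pos, kind, length, bases) events via a coordinate walk over
    expanded MD columns."""
    cols = expand_md(md)
    events: list[tuple] = []
    ref = pos
    qi = 0
    ci = 0
    for op, length in cigar:
        if op in "M=X":
            for _ in range(length):
                sym, _base = cols[ci]
                if sym == "X":
                    events.append((ref, "substitution", 1, seq[qi]))
                ref += 1
                qi += 1
                ci += 1
        elif op == "I":
            events.append((ref - 1, "insertion", length, seq[qi : qi + length]))
            qi += length
        elif op == "D":
            bases = "".join(cols[ci + k][1] for k in range(length))
            events.append((ref, "deletion", length, bases))
            ref += length
            ci += length
        elif op == "S":
            qi += length
        elif op == "N":
            ref += length
    return events


def oracle_window_filter(events: list[tuple], wstart: int, wend: int) -> list[tuple]:
    """The documented windowing rules, applied to oracle event tuples."""
    kept = []
    for ref_pos, kind, length, bases in events:
        if kind == "substitution" and wstart <= ref_pos <= wend:
            kept.append((ref_pos, kind, length, bases))
        elif kind == "deletion" and ref_pos <= wend and ref_pos + length - 1 >= wstart:
            kept.append((ref_pos, kind, length, bases))
        elif kind == "insertion" and wstart - 1 <= ref_pos <= wend:
            kept.append((ref_pos, kind, length, bases))
    return kept


def oracle_pairwise_auc(scores, labels) -> float:
    """AUC as the fraction of positive-negative pairs correctly ordered,
    ties counted one half (brute force over all pairs)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p, n in product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


def random_mutation_plan(rng, window_start: int, ref_seq: str):
    """Draw a random non-overlapping mutation plan over a reference window.

    Returns (events, ref_seq) where events are (ref_pos, kind, length, bases)
    tuples with deletion bases matching the reference.
    """
    n = len(ref_seq)
    wend = window_start + n - 1
    taken: set[int] = set()
    events: list[tuple] = []
    n_events = int(rng.integers(0, 5))
    attempts = 0
    while len(events) < n_events and attempts < 50:
        attempts += 1
        kind = ["insertion", "deletion", "substitution"][int(rng.integers(3))]
        if kind == "deletion":
            length = int(rng.integers(1, 4))
            if n <= length + 2:
                continue
            p = int(rng.integers(window_start + 1, wend - length))
            span = set(range(p, p + length))
            if span & taken:
                continue
            # reserve one base each side so two planned deletions never merge
            # into a single CIGAR D run (which would change event granularity)
            taken |= span | {p - 1, p + length}
            off = p - window_start
            events.append((p, "deletion", length, ref_seq[off : off + length]))
        elif kind == "substitution":
            p = int(rng.integers(window_start, wend + 1))
            if p in taken:
                continue
            taken.add(p)
            ref_base = ref_seq[p - window_start]
            alts = [b for b in "ACGT" if b != ref_base]
            events.append((p, "substitution", 1, alts[int(rng.integers(3))]))
        else:
            length = int(rng.integers(1, 3))
            p = int(rng.integers(window_start - 1, wend + 1))
            if p in taken or any(e[0] == p and e[1] == "insertion" for e in events):
                continue
            bases = "".join("ACGT"[int(rng.integers(4))] for _ in range(length))
            events.append((p, "insertion", length, bases))
    # an insertion anchored at a deleted position is contradictory
    deleted = {
        q for e in events if e[1] == "deletion" for q in range(e[0], e[0] + e[2])
    }
    events = [e for e in events if not (e[1] == "insertion" and e[0] in deleted)]
    return sorted(events)
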