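"""Indel-locus detection and CIGAR realignment around indels and STRs.

The pileup stops when at least one alignment carries an indel anchored at
the current position i, gathers every indel starting within the next x
positions (x = length of the largest indel anchored at i), and votes for
the start position j with the most support. Alignments whose indel is
anchored elsewhere are rewritten -- CIGAR only, never the bases -- so all
events share the anchor j. When a known STR covers the events, the base
before the STR start is chosen as j instead of voting. The locus interval
[j, k] then collects candidate haplotypes: reads fully covering the padded
window [j-5, k+5] contribute their aligned segment; reads that only
partially span the window have the dangling end soft-clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import ReadAlignment, STRAnnotation

FLANK = 5  # padding around the locus interval a read must fully cover

INSERTION = "I"
DELETION = "D"


@dataclass(frozen=True)
class IndelEvent:
    """One insertion/deletion in one alignment, anchored at the last
    reference base before the inserted/deleted sequence."""

    seq_name: str
    anchor: int
    kind: str  # INSERTION or DELETION
    length: int
    read: ReadAlignment

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("indel event with length < 1")


@dataclass(frozen=True)
class IndelLocus:
    """A single locus [start, end] collecting candidate haplotypes."""

    seq_name: str
    start: int  # chosen anchor j
    end: int    # position k (or the STR end when one is anchored)
    anchored_str: STRAnnotation | None = None

    @property
    def window_start(self) -> int:
        return self.start - FLANK

    @property
    def window_end(self) -> int:
        return self.end + FLANK


@dataclass(frozen=True)
class CandidateHaplotype:
    """Read segment aligned to a locus interval, with its qualities."""

    sequence: str
    qualities: tuple[int, ...]
    read_name: str
    sample_id: str = "sample"

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError("haplotype quality/sequence length mismatch")


def indel_events_of(alignment: ReadAlignment) -> list[IndelEvent]:
    """Extract every indel event from one alignment's CIGAR."""
    events = []
    ref = alignment.start
    for op, length in alignment.cigar:
        if op == "M":
            ref += length
        elif op == INSERTION:
            events.append(IndelEvent(alignment.seq_name, ref - 1, INSERTION, length, alignment))
        elif op == DELETION:
            events.append(IndelEvent(alignment.seq_name, ref - 1, DELETION, length, alignment))
            ref += length
    return events


def collect_indel_events(
    active_alignments: Sequence[ReadAlignment], position_i: int
) -> list[IndelEvent]:
    """All indel events anchored in [i, i+x], x = largest indel length at i.

    Returns an empty list when no alignment has an indel anchored at i.
    """
    all_events = [e for a in active_alignments for e in indel_events_of(a)]
    at_i = [e for e in all_events if e.anchor == position_i]
    if not at_i:
        return []
    x = max(e.length for e in at_i)
    return [e for e in all_events if position_i <= e.anchor <= position_i + x]


def vote_indel_start(events: Sequence[IndelEvent]) -> int:
    """Anchor supported by the most events; ties broken leftmost."""
    if not events:
        raise ValueError("cannot vote over zero indel events")
    counts: dict[int, int] = {}
    for e in events:
        counts[e.anchor] = counts.get(e.anchor, 0) + 1
    return min(counts, key=lambda a: (-counts[a], a))


def anchor_to_str(str_annotation: STRAnnotation) -> int:
    """STR-anchored start: the base before the repeat's first position,
    matching the VCF leading-base convention."""
    return str_annotation.first - 1


def events_in_str(events: Sequence[IndelEvent], str_annotation: STRAnnotation) -> list[IndelEvent]:
    return [e for e in events if str_annotation.contains_anchor(e.anchor)]


def str_exceeds_read_length(str_annotation: STRAnnotation, read_length: int) -> bool:
    """Repeats longer than the read length are excluded from analysis: no
    read can span them together with their flanks, so no haplotype can be
    collected and no call is attempted."""
    return str_annotation.span > read_length


def shifted_cigar(
    cigar: list[tuple[str, int]], event_anchor: int, start: int, kind: str,
    length: int, target_anchor: int,
) -> list[tuple[str, int]] | None:
    """CIGAR with the matching indel operation moved to ``target_anchor``.

    Returns None when the shift is infeasible (flanking match block too
    short, or no matching operation). Read- and reference-consuming totals
    are conserved: the shift moves bases between the two flanking match
    blocks only.
    """
    # locate the operation
    ref = start
    idx = None
    for i, (op, l) in enumerate(cigar):
        if op == "M":
            ref += l
        elif op in (INSERTION, DELETION):
            if ref - 1 == event_anchor and op == kind and l == length:
                idx = i
                break
            if op == DELETION:
                ref += l
    if idx is None:
        return None
    delta = target_anchor - event_anchor
    if delta == 0:
        return list(cigar)
    new = list(cigar)
    prev_i, next_i = idx - 1, idx + 1
    prev_op = new[prev_i] if prev_i >= 0 else None
    next_op = new[next_i] if next_i < len(new) else None
    if delta > 0:
        # shrink the following match block, grow (or create) the preceding one
        if next_op is None or next_op[0] != "M" or next_op[1] <= delta:
            return None
        new[next_i] = ("M", next_op[1] - delta)
        if prev_op is not None and prev_op[0] == "M":
            new[prev_i] = ("M", prev_op[1] + delta)
        else:
            new.insert(idx, ("M", delta))
    else:
        d = -delta
        if prev_op is None or prev_op[0] != "M" or prev_op[1] <= d:
            return None
        new[prev_i] = ("M", prev_op[1] - d)
        if next_op is not None and next_op[0] == "M":
            new[next_i] = ("M", next_op[1] + d)
        else:
            new.insert(idx + 1, ("M", d))
    return new


def realign_event(
    alignment: ReadAlignment, event: IndelEvent, target_j: int
) -> ReadAlignment:
    """Alignment with the event's indel operation re-anchored at target_j.

    Only the CIGAR changes; the read bases and leftmost start stay put.
    Infeasible shifts return the alignment unmodified with
    ``realignment_flagged`` set.
    """
    new_cigar = shifted_cigar(
        alignment.cigar, event.anchor, alignment.start, event.kind, event.length, target_j
    )
    out = alignment.copy()
    if new_cigar is None:
        out.realignment_flagged = True
    else:
        out.cigar = new_cigar
    return out


def define_locus(
    events: Sequence[IndelEvent],
    j: int,
    known_str: STRAnnotation | None = None,
    seq_name: str | None = None,
) -> IndelLocus:
    """Locus [j, k]: k is the end of the largest deletion plus one, or j+1
    when only insertions are present; a known STR extends the end so the
    whole repeat is treated as one locus."""
    if seq_name is None:
        seq_name = events[0].seq_name if events else (known_str.seq_name if known_str else None)
    deletions = [e.length for e in events if e.kind == DELETION and e.anchor == j]
    k = j + (max(deletions) + 1 if deletions else 1)
    if known_str is not None:
        k = max(k, known_str.last)
    return IndelLocus(seq_name, j, k, known_str)


def extract_haplotype(alignment: ReadAlignment, locus: IndelLocus) -> CandidateHaplotype:
    """Read segment (bases + qualities) aligned to [locus.start, locus.end],
    including insertions anchored inside the interval."""
    seq: list[str] = []
    quals: list[int] = []
    ref = alignment.start
    read = 0
    for op, length in alignment.cigar:
        if op == "S":
            read += length
        elif op == "M":
            for off in range(length):
                pos = ref + off
                if locus.start <= pos <= locus.end:
                    seq.append(alignment.bases[read + off])
                    quals.append(alignment.base_qualities[read + off])
            ref += length
            read += length
        elif op == INSERTION:
            anchor = ref - 1
            if locus.start <= anchor < locus.end:
                seq.extend(alignment.bases[read : read + length])
                quals.extend(alignment.base_qualities[read : read + length])
            read += length
        elif op == DELETION:
            ref += length
    return CandidateHaplotype("".join(seq), tuple(quals), alignment.read_name, alignment.sample_id)


def soft_clip_from(alignment: ReadAlignment, position: int) -> ReadAlignment:
    """Soft-clip everything aligned at reference positions >= position."""
    out = alignment.copy()
    new: list[tuple[str, int]] = []
    ref = out.start
    clipped = 0
    for op, length in out.cigar:
        if op == "S":
            if clipped:
                clipped += length
            else:
                new.append((op, length))
        elif op == "M":
            if ref + length <= position:
                new.append((op, length))
            else:
                keep = max(0, position - ref)
                if keep:
                    new.append((op, keep))
                clipped += length - keep
            ref += length
        elif op == INSERTION:
            if ref <= position:
                new.append((op, length))
            else:
                clipped += length
        elif op == DELETION:
            if ref + length <= position:
                new.append((op, length))
            ref += length
    if clipped:
        new.append(("S", clipped))
    out.cigar = _merge_cigar(new)
    return out


def soft_clip_through(alignment: ReadAlignment, position: int) -> ReadAlignment:
    """Soft-clip everything aligned at reference positions <= position; the
    leftmost start moves to the first retained reference base."""
    out = alignment.copy()
    new: list[tuple[str, int]] = []
    tail: list[tuple[str, int]] = []
    ref = out.start
    clipped = 0
    new_start = None
    for op, length in out.cigar:
        if op == "S":
            if new_start is None:
                clipped += length
            else:
                tail.append((op, length))
        elif op == "M":
            if ref + length - 1 <= position:
                clipped += length
            else:
                drop = max(0, position - ref + 1)
                clipped += drop
                if new_start is None:
                    new_start = ref + drop
                tail.append((op, length - drop))
            ref += length
        elif op == INSERTION:
            if new_start is None:
                clipped += length
            else:
                tail.append((op, length))
        elif op == DELETION:
            if ref > position and new_start is None:
                new_start = ref
            if new_start is not None and ref + length - 1 > position:
                tail.append((op, length))
            ref += length
    if clipped:
        new.append(("S", clipped))
    new.extend(tail)
    # leading/trailing deletions after clipping are meaningless
    out.cigar = _strip_edge_deletions(_merge_cigar(new))
    out.start = new_start if new_start is not None else out.end + 1
    return out


def _merge_cigar(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op, length in cigar:
        if length == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + length)
        else:
            merged.append((op, length))
    return merged


def _strip_edge_deletions(cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    ops = list(cigar)
    # drop D adjacent to the soft-clipped edge (first/last ref-consuming slot)
    def first_ref_idx(seq):
        for i, (op, _) in enumerate(seq):
            if op in ("M", "D"):
                return i
        return None

    i = first_ref_idx(ops)
    while i is not None and ops[i][0] == "D":
        del ops[i]
        i = first_ref_idx(ops)
    j = None
    for idx in range(len(ops) - 1, -1, -1):
        if ops[idx][0] in ("M", "D"):
            j = idx
            break
    while j is not None and ops[j][0] == "D":
        del ops[j]
        j = None
        for idx in range(len(ops) - 1, -1, -1):
            if ops[idx][0] in ("M", "D"):
                j = idx
                break
    return ops


def clip_or_extract(
    alignment: ReadAlignment, locus: IndelLocus
) -> tuple[CandidateHaplotype | None, ReadAlignment]:
    """Haplotype extraction for full-window reads, soft-clipping otherwise.

    Reads fully covering [start-FLANK, end+FLANK] yield their aligned
    segment over [start, end] as a candidate haplotype (alignment returned
    untouched). Reads only partially spanning the window get the partial
    end soft-clipped and contribute no haplotype.
    """
    ws, we = locus.window_start, locus.window_end
    if alignment.start <= ws and alignment.end >= we:
        return extract_haplotype(alignment, locus), alignment
    clipped = alignment
    if alignment.start > ws and alignment.end >= we:
        # left end dangles into the window
        clipped = soft_clip_through(clipped, min(we, clipped.end))
    elif alignment.end < we and alignment.start <= ws:
        clipped = soft_clip_from(clipped, max(ws, clipped.start))
    else:
        # read entirely inside the window: nothing spans, clip the overlap
        clipped = soft_clip_from(clipped, max(ws, clipped.start))
    return None, clipped
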