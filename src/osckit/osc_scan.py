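"""Detection and classification of out-of-frame stop codons (OSCs).

An OSC is a TAA/TAG/TGA triplet whose start offset is not congruent to
0 mod 3 — a stop that only becomes active after a reading-frame shift.
Composition confound checks (GC content, homopolymer runs) live here too.
"""

from __future__ import annotations

import dataclasses
import enum

from .sequence_core import CodingSequence, OscKitError, STOP_CODONS


class StopClass(enum.Enum):
    """The three stop triplets by their classical names."""

    OCHRE = "TAA"
    AMBER = "TAG"
    OPAL = "TGA"

    @classmethod
    def from_triplet(cls, triplet: str) -> "StopClass":
        for member in cls:
            if member.value == triplet:
                return member
        raise ValueError(f"{triplet!r} is not a stop triplet")


@dataclasses.dataclass(frozen=True)
class OutOfFrameStop:
    """One detected OSC.

    ``nt_offset`` is the 0-based offset of the triplet start; ``frame`` is
    ``nt_offset mod 3`` (1 or 2); ``codon_span`` is the pair of 1-based
    in-frame codon indices the triplet overlaps (always two distinct codons
    for offsets not divisible by 3, except at a sequence 3' edge).
    """

    nt_offset: int
    frame: int
    stop_class: StopClass
    codon_span: tuple[int, int]

    @property
    def triplet(self) -> str:
        return self.stop_class.value


@dataclasses.dataclass(frozen=True)
class HomopolymerRun:
    """A maximal single-base run. ``start`` is 1-based."""

    base: str
    start: int
    length: int


def _as_nt(seq: CodingSequence | str) -> str:
    return seq.nt if isinstance(seq, CodingSequence) else seq


def scan_oscs(
    cds: CodingSequence | str, frames: frozenset[int] | set[int] = frozenset({1, 2})
) -> list[OutOfFrameStop]:
    """Report every stop triplet fully inside the sequence in the given frames.

    Frames are offsets mod 3 relative to frame 0; only 1 and 2 are valid (an
    in-frame stop is not an OSC). Output is sorted by ``nt_offset`` then
    frame; triplets must lie fully within the sequence (no wrapping).
    """
    frames = set(frames)
    if not frames:
        raise OscKitError("empty frame set")
    if not frames <= {1, 2}:
        raise OscKitError(f"invalid frames {frames - {1, 2}}; only +1/+2 allowed")
    nt = _as_nt(cds)
    if len(nt) < 3:
        raise OscKitError("sequence shorter than 3 nt")
    hits: list[OutOfFrameStop] = []
    for offset in range(len(nt) - 2):
        frame = offset % 3
        if frame not in frames:
            continue
        triplet = nt[offset : offset + 3]
        if triplet in STOP_CODONS:
            span = (offset // 3 + 1, (offset + 2) // 3 + 1)
            hits.append(
                OutOfFrameStop(offset, frame, StopClass.from_triplet(triplet), span)
            )
    return hits


def count_by_stop_class(oscs: list[OutOfFrameStop]) -> dict[StopClass, int]:
    """Tally OSCs per stop class; every class is present in the result."""
    counts = {cls: 0 for cls in StopClass}
    for osc in oscs:
        counts[osc.stop_class] += 1
    return counts


def gc_content(cds: CodingSequence | str) -> float:
    nt = _as_nt(cds)
    if not nt:
        raise OscKitError("empty sequence")
    return (nt.count("G") + nt.count("C")) / len(nt)


def find_homopolymers(
    cds: CodingSequence | str, min_run: int = 2
) -> list[HomopolymerRun]:
    """All maximal single-base runs of length >= ``min_run``, sorted by start."""
    if min_run < 2:
        raise OscKitError(f"min_run must be >= 2, got {min_run}")
    nt = _as_nt(cds)
    runs: list[HomopolymerRun] = []
    i = 0
    while i < len(nt):
        j = i
        while j < len(nt) and nt[j] == nt[i]:
            j += 1
        if j - i >= min_run:
            runs.append(HomopolymerRun(nt[i], i + 1, j - i))
        i = j
    return runs
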