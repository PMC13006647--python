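"""Indel application, translational-outcome classification and spectra.

The central object is a :class:`Construct`: a coding sequence that may carry
an engineered net frameshift (e.g. a +1 single-base insertion) and whose
natural stop codon occupies its final three nucleotides. Applying a candidate
indel and fully translating the result classifies the event as
frame-restoring (gain of function), prematurely terminating, or
frame-disrupting — and transplanting events between a synonymous construct
pair at identical coordinates implements sequence-reconstruction analysis.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from .sequence_core import (
    CodingSequence,
    OscKitError,
    Peptide,
    STOP_CODONS,
    CODON_TO_AA,
    write_table,
    read_table,
)

INSERTION = "insertion"
DELETION = "deletion"


@dataclasses.dataclass(frozen=True)
class IndelEvent:
    """A single insertion or deletion.

    ``position`` is 1-based. For insertions the payload string is inserted
    immediately AFTER this position (0 inserts before the first base). For
    deletions it is the first deleted base and ``payload`` is the deleted
    length (>= 1).
    """

    kind: str
    position: int
    payload: str | int
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (INSERTION, DELETION):
            raise OscKitError(f"unknown indel kind {self.kind!r}")
        if self.kind == INSERTION:
            if not isinstance(self.payload, str) or not self.payload:
                raise OscKitError("insertion payload must be a nonempty string")
            if self.position < 0:
                raise OscKitError("insertion position must be >= 0")
        else:
            if not isinstance(self.payload, int) or self.payload < 1:
                raise OscKitError("deletion length must be an integer >= 1")
            if self.position < 1:
                raise OscKitError("deletion position must be >= 1")
        if not self.label:
            object.__setattr__(self, "label", self.default_label())

    @property
    def delta(self) -> int:
        """Signed length change caused by the event."""
        return len(self.payload) if self.kind == INSERTION else -int(self.payload)

    def default_label(self) -> str:
        if self.kind == INSERTION:
            return f"+{len(self.payload)}{self.payload}@{self.position}"
        return f"-{self.payload}@{self.position}"


@dataclasses.dataclass(frozen=True)
class Construct:
    """A coding construct with an optional engineered net frameshift.

    ``frameshift_offset`` is the net shift (0, 1 or 2 extra nucleotides)
    already engineered into ``cds`` relative to the in-frame gene it derives
    from. ``loop_codons`` is the 1-based wild-type codon range encoding the
    protein loop of interest, when one is tracked. The natural stop codon is
    the final three nucleotides of ``cds``.
    """

    cds: CodingSequence
    frameshift_offset: int = 0
    loop_codons: tuple[int, int] | None = None
    natural_stop_codon_index: int | None = None

    def __post_init__(self) -> None:
        if self.frameshift_offset not in (0, 1, 2):
            raise OscKitError("frameshift_offset must be 0, 1 or 2")
        if len(self.cds.nt) % 3 != self.frameshift_offset % 3:
            raise OscKitError(
                "construct length inconsistent with declared frameshift_offset"
            )
        if self.cds.nt[-3:] not in STOP_CODONS:
            raise OscKitError("construct must end in its natural stop codon")
        if self.natural_stop_codon_index is None:
            object.__setattr__(
                self,
                "natural_stop_codon_index",
                (len(self.cds.nt) - self.frameshift_offset) // 3,
            )

    @property
    def id(self) -> str:
        return self.cds.id


FUNCTIONAL_RESTORED = "functional_restored"
PREMATURE_STOP = "premature_stop"
FRAME_DISRUPTED = "frame_disrupted"


@dataclasses.dataclass(frozen=True)
class TranslationOutcome:
    classification: str
    peptide: Peptide
    first_stop_codon_index: int | None
    net_frame_shift: int
    loop_delta_aa: int | None


@dataclasses.dataclass(frozen=True)
class ReconstructionResult:
    event: IndelEvent
    source_construct_id: str
    host_construct_id: str
    outcome: TranslationOutcome
    permitted: bool


@dataclasses.dataclass(frozen=True)
class SpectrumEntry:
    site: int
    label: str
    kind: str
    count: int


@dataclasses.dataclass(frozen=True)
class IndelSpectrum:
    strain_id: str
    entries: tuple[SpectrumEntry, ...]
    n_total: int

    def percent(self, entry: SpectrumEntry) -> float:
        return 100.0 * entry.count / self.n_total

    @property
    def pct_insertions(self) -> float:
        n = sum(e.count for e in self.entries if e.kind == INSERTION)
        return 100.0 * n / self.n_total

    @property
    def pct_deletions(self) -> float:
        n = sum(e.count for e in self.entries if e.kind == DELETION)
        return 100.0 * n / self.n_total

    @property
    def sites(self) -> set[int]:
        return {e.site for e in self.entries}


@dataclasses.dataclass(frozen=True)
class SiteComparison:
    strain_a: str
    strain_b: str
    unique_to_a: frozenset[int]
    unique_to_b: frozenset[int]
    shared: frozenset[int]


def apply_indel(construct: "Construct | CodingSequence", event: IndelEvent) -> CodingSequence:
    """Apply ``event`` to the construct's sequence, returning the mutant.

    Pure length bookkeeping: bases outside the edit are unchanged.
    """
    cds = construct.cds if isinstance(construct, Construct) else construct
    nt = cds.nt
    if event.kind == INSERTION:
        if event.position > len(nt):
            raise OscKitError(
                f"insertion after position {event.position} beyond sequence end {len(nt)}"
            )
        out = nt[: event.position] + event.payload + nt[event.position :]
    else:
        end = event.position - 1 + int(event.payload)
        if end > len(nt):
            raise OscKitError(
                f"deletion of {event.payload} at position {event.position} runs past "
                f"sequence end {len(nt)}"
            )
        out = nt[: event.position - 1] + nt[end:]
    return CodingSequence(
        id=f"{cds.id}|{event.label}", nt=out, codon_table_id=cds.codon_table_id
    )


def normalize_event(nt: str | CodingSequence, event: IndelEvent) -> IndelEvent:
    """Left-align an event within a repeat run (mutant sequence is unchanged).

    Mirrors variant-call left-normalization: an ambiguous placement inside a
    homopolymer or repeat is reported once, at its leftmost equivalent
    position. The returned event keeps the original label's event description
    but uses the left-aligned site.
    """
    seq = nt.nt if isinstance(nt, CodingSequence) else nt
    if event.kind == DELETION:
        pos, k = event.position, int(event.payload)
        # shifting left by 1 is valid when the base entering the deleted
        # window from the left equals the base leaving it on the right
        while pos > 1 and seq[pos - 2] == seq[pos + k - 2]:
            pos -= 1
        if pos == event.position:
            return event
        return IndelEvent(DELETION, pos, k)
    pos, payload = event.position, str(event.payload)
    while pos > 0 and seq[pos - 1] == payload[-1]:
        payload = seq[pos - 1] + payload[:-1]
        pos -= 1
    if pos == event.position and payload == event.payload:
        return event
    return IndelEvent(INSERTION, pos, payload)


def classify_outcome(construct: Construct, mutant: CodingSequence) -> TranslationOutcome:
    """Classify a mutant by full translation from codon 1.

    - ``functional_restored``: net frame shift is 0 and the first in-frame
      stop is exactly the construct's natural stop (its final triplet) — the
      gain-of-function / selectable class.
    - ``premature_stop``: a stop codon is read before the natural stop.
    - ``frame_disrupted``: anything else (no stop before running off the
      sequence, or the natural stop destroyed), i.e. read-through.

    ``loop_delta_aa`` (set only for restored mutants) is the net amino-acid
    change of the tracked loop: (engineered shift + event length change) / 3,
    assuming both edits fall within the loop-encoding region.
    """
    nt = mutant.nt
    length = len(nt)
    net = length % 3  # wild-type gene length is a multiple of 3
    first_stop_nt: int | None = None
    aa_chars: list[str] = []
    for start in range(0, length - 2, 3):
        codon = nt[start : start + 3]
        if codon in STOP_CODONS:
            first_stop_nt = start
            break
        aa_chars.append(CODON_TO_AA[codon])
    peptide = Peptide(
        mutant.id,
        "".join(aa_chars),
        first_stop_nt is not None,
        first_stop_nt // 3 + 1 if first_stop_nt is not None else None,
    )
    natural_stop_nt = length - 3
    if first_stop_nt is None:
        classification = FRAME_DISRUPTED
    elif net == 0 and first_stop_nt == natural_stop_nt:
        classification = FUNCTIONAL_RESTORED
    elif first_stop_nt < natural_stop_nt:
        classification = PREMATURE_STOP
    else:  # net != 0 and a stop at/after the (unreadable) natural position
        classification = FRAME_DISRUPTED
    loop_delta: int | None = None
    if classification == FUNCTIONAL_RESTORED:
        delta = length - len(construct.cds.nt)
        loop_delta = (construct.frameshift_offset + delta) // 3
    return TranslationOutcome(
        classification=classification,
        peptide=peptide,
        first_stop_codon_index=peptide.stop_codon_index,
        net_frame_shift=net,
        loop_delta_aa=loop_delta,
    )


def reconstruct_in_host(
    event: IndelEvent, source: Construct, host: Construct
) -> ReconstructionResult:
    """Transplant an event observed in ``source`` into ``host`` at the same
    1-based coordinate and classify the outcome.

    Valid only for homologous constructs of equal length (e.g. a synonymous
    +OSC/−OSC pair), where identical coordinates define the site map.
    """
    if len(source.cds.nt) != len(host.cds.nt):
        raise OscKitError(
            "source and host constructs differ in length; no site correspondence"
        )
    mutant = apply_indel(host, event)
    outcome = classify_outcome(host, mutant)
    return ReconstructionResult(
        event=event,
        source_construct_id=source.id,
        host_construct_id=host.id,
        outcome=outcome,
        permitted=outcome.classification == FUNCTIONAL_RESTORED,
    )


def fraction_forbidden(
    events: Sequence[IndelEvent], source: Construct, host: Construct
) -> float:
    """Fraction of events that are NOT frame-restoring in ``host``."""
    if not events:
        raise OscKitError("empty event list")
    n_forbidden = sum(
        not reconstruct_in_host(e, source, host).permitted for e in events
    )
    return n_forbidden / len(events)


def summarize_spectrum(
    mutants: Iterable[tuple[str, IndelEvent]],
    sequences: dict[str, CodingSequence | str] | None = None,
    compare: tuple[str, str] | None = None,
) -> tuple[dict[str, IndelSpectrum], SiteComparison | None]:
    """Tally per-strain indel spectra and (optionally) compare two strains.

    When per-strain reference ``sequences`` are supplied, events are
    left-aligned before tallying so that ambiguous placements inside repeat
    runs collapse to one site. Percent-occurrence denominators are per-strain
    totals. ``compare`` names the two strains for unique/shared site sets
    (defaults to the pair when exactly two strains are present).
    """
    by_strain: dict[str, list[IndelEvent]] = {}
    for strain_id, event in mutants:
        if sequences is not None and strain_id in sequences:
            event = normalize_event(
                sequences[strain_id].nt
                if isinstance(sequences[strain_id], CodingSequence)
                else sequences[strain_id],
                event,
            )
        by_strain.setdefault(strain_id, []).append(event)
    spectra: dict[str, IndelSpectrum] = {}
    for strain_id, events in by_strain.items():
        tally: dict[tuple[int, str, str], int] = {}
        for e in events:
            key = (e.position, e.label, e.kind)
            tally[key] = tally.get(key, 0) + 1
        entries = tuple(
            SpectrumEntry(site, label, kind, count)
            for (site, label, kind), count in sorted(tally.items())
        )
        spectra[strain_id] = IndelSpectrum(strain_id, entries, len(events))
    comparison: SiteComparison | None = None
    if compare is None and len(spectra) == 2:
        compare = tuple(sorted(spectra))  # type: ignore[assignment]
    if compare is not None:
        a, b = compare
        if a not in spectra or b not in spectra:
            missing = {a, b} - set(spectra)
            raise OscKitError(f"unknown strain id(s) in comparison: {sorted(missing)}")
        sa, sb = spectra[a].sites, spectra[b].sites
        comparison = SiteComparison(
            a, b, frozenset(sa - sb), frozenset(sb - sa), frozenset(sa & sb)
        )
    return spectra, comparison


EVENT_COLUMNS = ["strain_id", "kind", "position_1based", "payload", "label"]


def write_events_tsv(
    mutants: Iterable[tuple[str, IndelEvent]], path: str | Path
) -> None:
    rows = [
        {
            "strain_id": strain,
            "kind": e.kind,
            "position_1based": e.position,
            "payload": e.payload,
            "label": e.label,
        }
        for strain, e in mutants
    ]
    write_table(rows, path, columns=EVENT_COLUMNS)


def read_events_tsv(path: str | Path) -> list[tuple[str, IndelEvent]]:
    df = read_table(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise OscKitError(f"{path}: missing event columns {sorted(missing)}")
    out: list[tuple[str, IndelEvent]] = []
    for row in df.itertuples(index=False):
        kind = str(row.kind)
        payload: str | int = (
            str(row.payload) if kind == INSERTION else int(row.payload)
        )
        out.append(
            (
                str(row.strain_id),
                IndelEvent(kind, int(row.position_1based), payload, str(row.label)),
            )
        )
    return out
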