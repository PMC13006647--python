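"""Core sequence model: coding sequences, codon-table translation and FASTA/TSV I/O.

Coordinate conventions used across the package: internal coordinates are
0-based half-open; every coordinate that crosses an I/O boundary (TSV, CLI,
reports) is 1-based inclusive. Translation uses NCBI table 11
(bacterial/plastid) with no start-codon special-casing and no read-through.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

TRANSL_TABLE_ID = 11

_TABLE = CodonTable.unambiguous_dna_by_id[TRANSL_TABLE_ID]

#: The three translational stop triplets (TAA, TAG, TGA).
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: Sense codon -> one-letter amino acid, table 11.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: One-letter amino acid -> tuple of its sense codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

VALID_BASES = frozenset("ACGT")


class OscKitError(Exception):
    """Base class for all package errors."""


class FastaParseError(OscKitError):
    pass


class AlphabetError(OscKitError):
    pass


class FrameError(OscKitError):
    pass


@dataclasses.dataclass(frozen=True)
class CodingSequence:
    """A nucleotide sequence treated as (part of) a coding region.

    ``nt`` is uppercase A/C/G/T. Scanning operations tolerate any length >= 3;
    ORF-mode operations (translation) additionally require a multiple of 3.
    """

    id: str
    nt: str
    codon_table_id: int = TRANSL_TABLE_ID
    description: str = ""

    def __len__(self) -> int:
        return len(self.nt)

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3

    def codon(self, index: int) -> str:
        """Return the in-frame codon at 1-based ``index``."""
        if not 1 <= index <= self.n_codons:
            raise IndexError(f"codon index {index} out of range 1..{self.n_codons}")
        return self.nt[3 * (index - 1) : 3 * index]

    def codons(self) -> list[str]:
        return [self.nt[i : i + 3] for i in range(0, 3 * self.n_codons, 3)]


@dataclasses.dataclass(frozen=True)
class Peptide:
    """A translated amino-acid sequence (no stop symbol in ``aa``).

    ``stop_codon_index`` is the 1-based codon index of the terminating stop
    when ``terminated`` is true.
    """

    id: str
    aa: str
    terminated: bool
    stop_codon_index: int | None = None

    def __len__(self) -> int:
        return len(self.aa)


def normalize_nt(nt: str, *, strict: bool = True, seq_id: str = "?") -> str:
    """Uppercase ``nt``; with ``strict`` reject any non-ACGT character.

    The error names the offending sequence id and 1-based position. With
    ``strict=False`` ambiguous characters are kept (uppercased) and it is the
    caller's responsibility to mask windows containing them.
    """
    up = nt.upper()
    if strict:
        for i, base in enumerate(up):
            if base not in VALID_BASES:
                raise AlphabetError(
                    f"sequence {seq_id!r}: invalid base {base!r} at position {i + 1}"
                )
    return up


def read_fasta(path: str | Path, *, strict: bool = True) -> list[CodingSequence]:
    """Read a (multi-)FASTA file into :class:`CodingSequence` records.

    Order-preserving; duplicate ids raise. Sequences are uppercased; with
    ``strict`` any non-ACGT base raises :class:`AlphabetError` naming the
    record and position.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"no such file: {path}")
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: not FASTA (first record lacks '>')")
    records: list[CodingSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        nt = normalize_nt(str(rec.seq), strict=strict, seq_id=rec.id)
        records.append(
            CodingSequence(id=rec.id, nt=nt, description=rec.description)
        )
    return records


def write_fasta(seqs: Iterable[CodingSequence], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in seqs:
            header = s.id if not s.description or s.description == s.id else s.description
            fh.write(f">{header}\n")
            for i in range(0, len(s.nt), width):
                fh.write(s.nt[i : i + width] + "\n")


def translate(cds: CodingSequence, through_stop: bool = False) -> Peptide:
    """Translate in frame 0 from position 1 under the sequence's codon table.

    Stops at the first stop codon unless ``through_stop``; in that mode stop
    codons are rendered as ``*`` and ``terminated`` reports whether any stop
    was seen (``stop_codon_index`` is the first one).
    """
    nt = cds.nt
    if len(nt) % 3 != 0:
        raise FrameError(
            f"sequence {cds.id!r}: length {len(nt)} is not a multiple of 3"
        )
    if len(nt) < 3:
        raise FrameError(f"sequence {cds.id!r}: too short to translate")
    aa_chars: list[str] = []
    first_stop: int | None = None
    for k in range(len(nt) // 3):
        codon = nt[3 * k : 3 * k + 3]
        if codon in STOP_CODONS:
            if first_stop is None:
                first_stop = k + 1
            if not through_stop:
                break
            aa_chars.append("*")
        else:
            try:
                aa_chars.append(CODON_TO_AA[codon])
            except KeyError:
                raise AlphabetError(
                    f"sequence {cds.id!r}: untranslatable codon {codon!r} at codon {k + 1}"
                ) from None
    if through_stop:
        aa = "".join(aa_chars)
        return Peptide(cds.id, aa, first_stop is not None, first_stop)
    return Peptide(cds.id, "".join(aa_chars), first_stop is not None, first_stop)


def write_table(
    records: Sequence[dict] | pd.DataFrame,
    path: str | Path,
    *,
    columns: Sequence[str] | None = None,
    float_format: str = "%.6g",
) -> None:
    """Write tabular records as a TSV with header.

    Column order follows ``columns`` when given, otherwise the key order of
    the first record (or the DataFrame's columns). Floats are serialized with
    6 significant digits; decimal separator is always '.'.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        if columns is not None:
            df = df[list(columns)]
    else:
        if columns is None:
            columns = list(records[0].keys()) if records else []
        df = pd.DataFrame(list(records), columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
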