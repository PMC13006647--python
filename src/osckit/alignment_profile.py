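"""Protein multiple-alignment profiling.

Column-wise residue frequencies and conservation calls, information content
in bits, gap-aware residue<->column coordinate mapping, anchor-delimited
loop-length extraction with taxon stratification, and overlay of
out-of-frame stop codons onto alignment columns.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO

from .osc_scan import OutOfFrameStop
from .sequence_core import OscKitError, read_table

GAP = "-"

#: log2 of the amino-acid alphabet size; the maximum per-column information.
MAX_BITS = math.log2(20)


@dataclasses.dataclass(frozen=True)
class ProteinAlignment:
    """Rows of equal-length aligned amino-acid strings (gap '-').

    ``taxon_map`` optionally assigns each sequence id a (domain, phylum)
    pair for stratified summaries.
    """

    rows: tuple[tuple[str, str], ...]
    taxon_map: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise OscKitError("alignment has no rows")
        width = len(self.rows[0][1])
        if width == 0:
            raise OscKitError("zero-width alignment")
        for seq_id, aligned in self.rows:
            if len(aligned) != width:
                raise OscKitError(f"row {seq_id!r} has length {len(aligned)} != {width}")
        ids = [r[0] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise OscKitError("duplicate sequence ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def row(self, seq_id: str) -> str:
        for rid, aligned in self.rows:
            if rid == seq_id:
                return aligned
        raise OscKitError(f"no row with id {seq_id!r}")

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.rows]


@dataclasses.dataclass(frozen=True)
class ColumnProfile:
    """Per-column summary.

    ``frequencies`` are fractions of non-gap residues; ``consensus_fraction``
    is the consensus count over ALL rows (a gap counts against conservation —
    switch via :meth:`is_conserved`'s ``include_gaps``). ``tie`` flags a
    consensus decided lexicographically among equally frequent residues.
    """

    column_index: int
    frequencies: Mapping[str, float]
    gap_fraction: float
    consensus: str | None
    consensus_count: int
    n_rows: int
    tie: bool = False

    @property
    def n_residues(self) -> int:
        return self.n_rows - round(self.gap_fraction * self.n_rows)

    @property
    def consensus_fraction(self) -> float:
        return self.consensus_count / self.n_rows

    def is_conserved(self, threshold: float = 0.5, include_gaps: bool = True) -> bool:
        """Strict-majority conservation call (> threshold, not >=)."""
        if self.consensus is None:
            return False
        denom = self.n_rows if include_gaps else self.n_residues
        if denom == 0:
            return False
        return self.consensus_count / denom > threshold


@dataclasses.dataclass(frozen=True)
class LoopRegion:
    """An anchor-delimited alignment span; columns are 1-based inclusive."""

    start_column: int
    end_column: int
    reference_id: str | None = None
    start_anchor: int | None = None  # 1-based reference residue indices
    end_anchor: int | None = None

    def __post_init__(self) -> None:
        if self.start_column > self.end_column:
            raise OscKitError("loop start column after end column")


def read_alignment(
    path: str | Path,
    fmt: str | None = None,
    taxon_map: Mapping[str, tuple[str, str]] | None = None,
) -> ProteinAlignment:
    """Read an aligned FASTA or Clustal file (format guessed from extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix in {".aln", ".clustal", ".clw"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    return ProteinAlignment(rows, taxon_map)


def read_taxon_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns seq_id, domain, phylum."""
    df = read_table(path)
    for col in ("seq_id", "domain", "phylum"):
        if col not in df.columns:
            raise OscKitError(f"{path}: taxon map missing column {col!r}")
    return {
        str(r.seq_id): (str(r.domain), str(r.phylum))
        for r in df.itertuples(index=False)
    }


def column_profiles(aln: ProteinAlignment) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per alignment column.

    Consensus is the most frequent residue; ties are broken toward the
    lexicographically smallest residue and flagged.
    """
    n = aln.n_rows
    profiles: list[ColumnProfile] = []
    for col in range(aln.n_cols):
        counts: dict[str, int] = {}
        gaps = 0
        for _, aligned in aln.rows:
            ch = aligned[col]
            if ch == GAP:
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        n_res = n - gaps
        if n_res == 0:
            profiles.append(
                ColumnProfile(col + 1, {}, 1.0, None, 0, n)
            )
            continue
        freqs = {aa: c / n_res for aa, c in sorted(counts.items())}
        best = max(counts.values())
        winners = sorted(aa for aa, c in counts.items() if c == best)
        profiles.append(
            ColumnProfile(
                column_index=col + 1,
                frequencies=freqs,
                gap_fraction=gaps / n,
                consensus=winners[0],
                consensus_count=best,
                n_rows=n,
                tie=len(winners) > 1,
            )
        )
    return profiles


def information_bits(
    profile: ColumnProfile,
    n_sequences: int | None = None,
    small_sample_correction: bool = False,
) -> float:
    """Information content of a column: log2(20) − Shannon entropy (bits).

    The optional small-sample correction subtracts e_n = 19 / (2·ln2·n); it
    is OFF by default. Result is floored at 0; an all-gap column scores 0.
    """
    if not profile.frequencies:
        return 0.0
    entropy = -sum(f * math.log2(f) for f in profile.frequencies.values() if f > 0)
    bits = MAX_BITS - entropy
    if small_sample_correction:
        n = n_sequences if n_sequences is not None else profile.n_residues
        if n < 1:
            raise OscKitError("n_sequences must be >= 1 for the correction")
        bits -= 19.0 / (2.0 * math.log(2) * n)
    return max(bits, 0.0)


def map_residue_to_column(aln: ProteinAlignment, seq_id: str, residue_index: int) -> int:
    """1-based column holding the ``residue_index``-th non-gap character."""
    row = aln.row(seq_id)
    if residue_index < 1:
        raise OscKitError(f"residue index must be >= 1, got {residue_index}")
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == residue_index:
                return col
    raise OscKitError(
        f"row {seq_id!r} has only {seen} residues; no residue {residue_index}"
    )


def map_column_to_residue(aln: ProteinAlignment, seq_id: str, column: int) -> int | None:
    """Inverse of :func:`map_residue_to_column`; None if the row is gapped there."""
    row = aln.row(seq_id)
    if not 1 <= column <= len(row):
        raise OscKitError(f"column {column} out of range 1..{len(row)}")
    if row[column - 1] == GAP:
        return None
    return sum(1 for ch in row[:column] if ch != GAP)


def loop_region_from_anchors(
    aln: ProteinAlignment, reference_id: str, start_residue: int, end_residue: int
) -> LoopRegion:
    """Build a loop span from two anchor residues of the reference row."""
    start_col = map_residue_to_column(aln, reference_id, start_residue)
    end_col = map_residue_to_column(aln, reference_id, end_residue)
    return LoopRegion(start_col, end_col, reference_id, start_residue, end_residue)


def loop_lengths(aln: ProteinAlignment, loop: LoopRegion) -> dict[str, int]:
    """Per-row count of non-gap residues in the loop span, anchors included."""
    if not (1 <= loop.start_column <= loop.end_column <= aln.n_cols):
        raise OscKitError(
            f"loop columns {loop.start_column}..{loop.end_column} outside alignment "
            f"width {aln.n_cols}"
        )
    lo, hi = loop.start_column - 1, loop.end_column
    return {
        seq_id: sum(1 for ch in aligned[lo:hi] if ch != GAP)
        for seq_id, aligned in aln.rows
    }


def loop_length_by_taxon(
    lengths: Mapping[str, int],
    taxon_map: Mapping[str, tuple[str, str]] | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts per (loop length, taxon) and within-taxon percentages.

    Sequences missing from the taxon map fall into "unassigned". The second
    table's columns each sum to 100.
    """
    def taxon_of(seq_id: str) -> str:
        if taxon_map is None or seq_id not in taxon_map:
            return "unassigned"
        domain, phylum = taxon_map[seq_id]
        return f"{domain}/{phylum}"

    records = [
        {"loop_length": ln, "taxon": taxon_of(sid)} for sid, ln in lengths.items()
    ]
    df = pd.DataFrame(records)
    counts = (
        df.groupby(["loop_length", "taxon"]).size().unstack(fill_value=0).sort_index()
    )
    pct = 100.0 * counts / counts.sum(axis=0)
    return counts, pct


def overlay_oscs(
    profiles: Sequence[ColumnProfile],
    oscs: Iterable[OutOfFrameStop],
    reference_id: str,
    aln: ProteinAlignment,
    threshold: float = 0.5,
    include_gaps: bool = True,
) -> tuple[list[dict], int, int]:
    """Annotate each OSC with its alignment columns and conservation status.

    Each overlapped in-frame codon maps (via the reference row) to one
    alignment column; an OSC counts as conserved when ANY overlapped codon's
    column passes the strict-majority rule. Returns (rows, n_conserved,
    n_total).
    """
    if reference_id not in aln.ids:
        raise OscKitError(f"reference {reference_id!r} not in alignment")
    rows: list[dict] = []
    n_conserved = 0
    oscs = list(oscs)
    for osc in oscs:
        columns: list[int] = []
        conserved_flags: list[bool] = []
        for codon_index in range(osc.codon_span[0], osc.codon_span[1] + 1):
            col = map_residue_to_column(aln, reference_id, codon_index)
            columns.append(col)
            conserved_flags.append(
                profiles[col - 1].is_conserved(threshold, include_gaps)
            )
        conserved = any(conserved_flags)
        n_conserved += conserved
        rows.append(
            {
                "nt_offset_1based": osc.nt_offset + 1,
                "frame": osc.frame,
                "stop_class": osc.stop_class.name.lower(),
                "codon_start": osc.codon_span[0],
                "codon_end": osc.codon_span[1],
                "columns": ",".join(str(c) for c in columns),
                "conserved": conserved,
            }
        )
    return rows, n_conserved, len(oscs)
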