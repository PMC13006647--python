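"""Codon-space likelihood that an amino-acid pair's junction hides a stop.

For an ordered pair of amino acids encoded by adjacent codons c1 c2, the two
out-of-frame triplets fully inside the 6-nt junction are
offset +1 (c1[2] c1[3] c2[1]) and offset +2 (c1[3] c2[1] c2[2]). The pair
probability is the usage-weighted chance that at least one of them is a stop
triplet. Two position-level summaries over an alignment column pair are
provided: frequency-weighted over all amino-acid pairs, and the mean over
the observed per-sequence pairs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

from .alignment_profile import ColumnProfile, ProteinAlignment, GAP
from .sequence_core import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    OscKitError,
    STOP_CODONS,
    read_table,
)


@dataclasses.dataclass(frozen=True)
class CodonUsage:
    """Per-amino-acid normalized codon weights over the sense codons."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for aa, codons in AA_TO_CODONS.items():
            missing = [c for c in codons if c not in self.weights]
            if missing:
                raise OscKitError(f"usage missing codons for {aa}: {missing}")
            total = sum(self.weights[c] for c in codons)
            if abs(total - 1.0) > 1e-9:
                raise OscKitError(
                    f"usage weights for {aa} sum to {total}, expected 1"
                )
            if any(self.weights[c] < 0 for c in codons):
                raise OscKitError(f"negative usage weight for {aa}")

    @classmethod
    def uniform(cls) -> "CodonUsage":
        weights = {
            c: 1.0 / len(codons)
            for codons in AA_TO_CODONS.values()
            for c in codons
        }
        return cls(weights)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsage":
        """Read codon, amino_acid, weight columns; renormalize per amino acid."""
        df = read_table(path)
        for col in ("codon", "amino_acid", "weight"):
            if col not in df.columns:
                raise OscKitError(f"{path}: usage table missing column {col!r}")
        raw = {str(r.codon).upper(): float(r.weight) for r in df.itertuples(index=False)}
        weights: dict[str, float] = {}
        for aa, codons in AA_TO_CODONS.items():
            total = sum(raw.get(c, 0.0) for c in codons)
            if total <= 0:
                raise OscKitError(f"{path}: no positive weight for amino acid {aa}")
            for c in codons:
                weights[c] = raw.get(c, 0.0) / total
        return cls(weights)

    def codons_for(self, aa: str) -> list[tuple[str, float]]:
        if aa not in AA_TO_CODONS:
            raise OscKitError(f"unknown amino acid {aa!r}")
        return [(c, self.weights[c]) for c in AA_TO_CODONS[aa]]


@dataclasses.dataclass(frozen=True)
class JunctionLikelihood:
    aa_pair: tuple[str, str]
    probability: float
    frame_breakdown: Mapping[int, float]


def pair_osc_probability(
    aa1: str, aa2: str, usage: CodonUsage | None = None
) -> JunctionLikelihood:
    """Probability that the c1 c2 junction contains >= 1 out-of-frame stop.

    Only the two triplets fully inside the 6-nt pair are considered; windows
    reaching into neighboring codons are excluded. The union probability is
    reported, with per-frame parts in ``frame_breakdown``.
    """
    usage = usage or CodonUsage.uniform()
    p_union = p1 = p2 = 0.0
    for c1, w1 in usage.codons_for(aa1):
        for c2, w2 in usage.codons_for(aa2):
            w = w1 * w2
            stop1 = c1[1:] + c2[0] in STOP_CODONS
            stop2 = c1[2] + c2[:2] in STOP_CODONS
            if stop1:
                p1 += w
            if stop2:
                p2 += w
            if stop1 or stop2:
                p_union += w
    return JunctionLikelihood((aa1, aa2), p_union, {1: p1, 2: p2})


def positional_likelihood_weighted(
    profile_i: ColumnProfile,
    profile_j: ColumnProfile,
    usage: CodonUsage | None = None,
) -> float:
    """Frequency-weighted junction-stop probability over all amino-acid pairs.

    Gap entries are already excluded from profile frequencies (which are
    normalized over residues).
    """
    if not profile_i.frequencies or not profile_j.frequencies:
        raise OscKitError("all-gap column has no amino-acid frequencies")
    usage = usage or CodonUsage.uniform()
    total = 0.0
    for a, fa in profile_i.frequencies.items():
        for b, fb in profile_j.frequencies.items():
            total += fa * fb * pair_osc_probability(a, b, usage).probability
    return total


def positional_likelihood_observed(
    aln: ProteinAlignment,
    col_i: int,
    col_j: int,
    usage: CodonUsage | None = None,
) -> tuple[float, list[tuple[str, str, str, float]]]:
    """Mean junction-stop probability over the observed per-sequence pairs.

    Rows gapped at either column are excluded (non-occurring pairs do not
    contribute). Returns the mean and the per-sequence table
    (seq_id, aa_i, aa_j, probability).
    """
    for col in (col_i, col_j):
        if not 1 <= col <= aln.n_cols:
            raise OscKitError(f"column {col} out of range 1..{aln.n_cols}")
    usage = usage or CodonUsage.uniform()
    per_seq: list[tuple[str, str, str, float]] = []
    cache: dict[tuple[str, str], float] = {}
    for seq_id, aligned in aln.rows:
        a, b = aligned[col_i - 1], aligned[col_j - 1]
        if a == GAP or b == GAP:
            continue
        if (a, b) not in cache:
            cache[(a, b)] = pair_osc_probability(a, b, usage).probability
        per_seq.append((seq_id, a, b, cache[(a, b)]))
    if not per_seq:
        raise OscKitError("all rows gapped at the requested columns")
    mean = sum(p for *_, p in per_seq) / len(per_seq)
    return mean, per_seq


@dataclasses.dataclass(frozen=True)
class PairPattern:
    aa_pair: tuple[str, str]
    pattern1: str
    pattern2: str
    tags: tuple[str, ...]


def codon_pattern(aa: str) -> str:
    """Positional nucleotide pattern shared by every codon of ``aa``.

    Positions where all codons agree show the base; others show 'N'
    (e.g. lysine -> "AAN", leucine -> "NTN").
    """
    codons = AA_TO_CODONS.get(aa)
    if not codons:
        raise OscKitError(f"unknown amino acid {aa!r}")
    pattern = []
    for pos in range(3):
        bases = {c[pos] for c in codons}
        pattern.append(bases.pop() if len(bases) == 1 else "N")
    return "".join(pattern)


def classify_pair_pattern(aa1: str, aa2: str) -> PairPattern:
    """Tag pairs whose codon patterns guarantee junction-stop potential.

    The "NTN|AAN" tag marks a middle-T first amino acid followed by one whose
    codons all start AA — the combination that makes an out-of-frame TAA/TGA
    likely regardless of codon choice.
    """
    p1, p2 = codon_pattern(aa1), codon_pattern(aa2)
    tags: list[str] = []
    if p1[1] == "T" and p2[:2] == "AA":
        tags.append("NTN|AAN")
    return PairPattern((aa1, aa2), p1, p2, tuple(tags))


def all_pair_probabilities(usage: CodonUsage | None = None) -> dict[tuple[str, str], float]:
    """Junction-stop probability for all 400 ordered amino-acid pairs."""
    usage = usage or CodonUsage.uniform()
    return {
        (a, b): pair_osc_probability(a, b, usage).probability
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
    }
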