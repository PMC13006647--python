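"""Seeded generators for every input the analysis stages consume.

All generators are pure functions of their arguments (seed included):
repeated calls with the same configuration produce byte-identical output.
Each generator owns its own random stream, so adding a call does not perturb
other generators at the same seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np

from .alignment_profile import ProteinAlignment
from .indel_engine import (
    Construct,
    FUNCTIONAL_RESTORED,
    IndelEvent,
    INSERTION,
    apply_indel,
    classify_outcome,
)
from .mutagenesis_stats import FluctuationDataset, SpmTimeSeries
from .osc_scan import scan_oscs
from .sequence_core import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    CODON_TO_AA,
    CodingSequence,
    OscKitError,
    SENSE_CODONS,
    translate,
)


class GenerationError(OscKitError):
    pass


class InfeasibleRecodingError(OscKitError):
    def __init__(self, message: str, stuck_osc_offsets: list[int]):
        super().__init__(message)
        self.stuck_osc_offsets = stuck_osc_offsets


@dataclasses.dataclass(frozen=True)
class ConstructPair:
    """A synonymous +OSC/−OSC pair: same protein, same length, OSC-free region
    in the minus variant."""

    plus_osc: Construct
    minus_osc: Construct
    osc_positions_removed: tuple[int, ...]
    region_codons: tuple[int, int]


def _max_run(nt: str) -> int:
    best = run = 1
    for a, b in zip(nt, nt[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


_GC_COUNT = {c: c.count("G") + c.count("C") for c in SENSE_CODONS}
_NON_STOP = tuple(c for c in SENSE_CODONS)  # sense codons only, no stops


def gen_coding_sequence(
    seed: int,
    n_codons: int,
    gc_target: float = 0.5,
    forbid_homopolymers_over: int | None = None,
    seq_id: str | None = None,
    max_attempts: int = 500,
) -> CodingSequence:
    """Random ORF: starts ATG, single terminal in-frame stop, no internal stops.

    Internal codons are drawn from the sense codons with an exponential tilt
    on codon GC that is adapted between attempts until whole-sequence GC lands
    within +/-0.05 of ``gc_target``. An optional maximal-homopolymer cap is
    enforced by rejection. Deterministic in ``seed``.
    """
    if n_codons < 3:
        raise GenerationError("need at least 3 codons (start, one internal, stop)")
    if not 0.0 < gc_target < 1.0:
        raise GenerationError("gc_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    gc = np.array([_GC_COUNT[c] for c in _NON_STOP], dtype=float)
    theta = 0.0
    last_gc = None
    for _ in range(max_attempts):
        w = np.exp(theta * gc)
        w /= w.sum()
        idx = rng.choice(len(_NON_STOP), size=n_codons - 2, p=w)
        nt = "ATG" + "".join(_NON_STOP[i] for i in idx) + "TAA"
        frac_gc = (nt.count("G") + nt.count("C")) / len(nt)
        last_gc = frac_gc
        if abs(frac_gc - gc_target) > 0.05:
            theta += 4.0 * (gc_target - frac_gc)
            continue
        if (
            forbid_homopolymers_over is not None
            and _max_run(nt) > forbid_homopolymers_over
        ):
            continue
        cds = CodingSequence(id=seq_id or f"synth_{seed}_{n_codons}", nt=nt)
        return cds
    raise GenerationError(
        f"could not satisfy constraints after {max_attempts} attempts "
        f"(last GC {last_gc:.3f}, target {gc_target})"
    )


def _region_osc_offsets(nt: str, region_nt: tuple[int, int]) -> list[int]:
    """Offsets of OSC triplets overlapping the half-open nt span."""
    lo, hi = region_nt
    return [
        o.nt_offset
        for o in scan_oscs(nt)
        if o.nt_offset < hi and o.nt_offset + 3 > lo
    ]


def remove_oscs_synonymously(
    cds: CodingSequence,
    region: tuple[int, int],
    max_changes: int | None = None,
) -> ConstructPair:
    """Recode codons in ``region`` (1-based, inclusive) to clear its OSCs.

    Searches synonymous codon assignments by increasing number of changed
    codons, so the returned minus variant uses the minimal number of codon
    changes; ties prefer fewest nucleotide changes, then the
    lexicographically smallest sequence. Raises
    :class:`InfeasibleRecodingError` (listing the stuck OSC offsets) when no
    synonymous assignment clears the region.
    """
    start_codon, end_codon = region
    if not 1 <= start_codon <= end_codon <= cds.n_codons:
        raise OscKitError(f"region {region} outside 1..{cds.n_codons}")
    region_nt = (3 * (start_codon - 1), 3 * end_codon)
    nt = cds.nt
    if not _region_osc_offsets(nt, region_nt):
        return _build_pair(cds, cds, region, ())

    positions = list(range(start_codon, end_codon + 1))
    if max_changes is None:
        max_changes = len(positions)

    def alternatives(codon_index: int) -> list[str]:
        codon = cds.codon(codon_index)
        return [c for c in AA_TO_CODONS[CODON_TO_AA[codon]] if c != codon]

    best: tuple[int, str] | None = None  # (nt changes, sequence)
    for k in range(1, max_changes + 1):
        for combo in itertools.combinations(positions, k):
            alt_lists = [alternatives(p) for p in combo]
            if any(not alts for alts in alt_lists):
                continue
            for choice in itertools.product(*alt_lists):
                cand = list(nt)
                for p, codon in zip(combo, choice):
                    cand[3 * (p - 1) : 3 * p] = codon
                cand_nt = "".join(cand)
                if _region_osc_offsets(cand_nt, region_nt):
                    continue
                n_changes = sum(a != b for a, b in zip(nt, cand_nt))
                key = (n_changes, cand_nt)
                if best is None or key < best:
                    best = key
        if best is not None:
            break
    if best is None:
        stuck = _stuck_oscs(cds, region, region_nt)
        raise InfeasibleRecodingError(
            f"no synonymous recoding of codons {start_codon}..{end_codon} removes "
            f"all OSCs; stuck OSC offsets (0-based): {stuck}",
            stuck,
        )
    minus = CodingSequence(
        id=f"{cds.id}_minusOSC", nt=best[1], codon_table_id=cds.codon_table_id
    )
    removed = tuple(_region_osc_offsets(nt, region_nt))
    return _build_pair(cds, minus, region, removed)


def _stuck_oscs(
    cds: CodingSequence, region: tuple[int, int], region_nt: tuple[int, int]
) -> list[int]:
    """OSC offsets present in every synonymous assignment of the region.

    Exhaustive over the full region product; intended for the short regions
    this package works with (falls back to the original's OSCs beyond ~6
    codons).
    """
    start_codon, end_codon = region
    positions = list(range(start_codon, end_codon + 1))
    if end_codon - start_codon + 1 > 6:
        return _region_osc_offsets(cds.nt, region_nt)
    options = [AA_TO_CODONS[CODON_TO_AA[cds.codon(p)]] for p in positions]
    stuck: set[int] | None = None
    for choice in itertools.product(*options):
        cand = list(cds.nt)
        for p, codon in zip(positions, choice):
            cand[3 * (p - 1) : 3 * p] = codon
        offsets = set(_region_osc_offsets("".join(cand), region_nt))
        stuck = offsets if stuck is None else stuck & offsets
        if not stuck:
            break
    return sorted(stuck or ())


def _build_pair(
    plus: CodingSequence,
    minus: CodingSequence,
    region: tuple[int, int],
    removed: tuple[int, ...],
) -> ConstructPair:
    if translate(plus).aa != translate(minus).aa:
        raise OscKitError("recoding changed the protein")  # pragma: no cover
    return ConstructPair(
        plus_osc=Construct(plus),
        minus_osc=Construct(minus),
        osc_positions_removed=removed,
        region_codons=region,
    )


def introduce_frameshift(
    cds: CodingSequence,
    codon_index: int,
    base: str = "T",
    loop_codons: tuple[int, int] | None = None,
) -> Construct:
    """Insert one base immediately after ``codon_index``, a +1 frameshift."""
    if not 1 <= codon_index <= cds.n_codons:
        raise OscKitError(f"codon index {codon_index} out of range 1..{cds.n_codons}")
    if len(base) != 1 or base not in "ACGT":
        raise OscKitError(f"frameshift base must be one of ACGT, got {base!r}")
    pos = 3 * codon_index
    shifted = CodingSequence(
        id=f"{cds.id}+1{base}",
        nt=cds.nt[:pos] + base + cds.nt[pos:],
        codon_table_id=cds.codon_table_id,
    )
    return Construct(
        cds=shifted,
        frameshift_offset=1,
        loop_codons=loop_codons,
        natural_stop_codon_index=cds.n_codons,
    )


def build_frameshifted_pair(
    cds: CodingSequence,
    region: tuple[int, int],
    frameshift_codon: int,
    base: str = "T",
    loop_codons: tuple[int, int] | None = None,
) -> tuple[Construct, Construct, ConstructPair]:
    """Convenience: clear the region's OSCs, then put the same +1 frameshift
    into both variants; returns (+OSC construct, −OSC construct, pair)."""
    pair = remove_oscs_synonymously(cds, region)
    plus = introduce_frameshift(
        pair.plus_osc.cds, frameshift_codon, base, loop_codons
    )
    minus = introduce_frameshift(
        pair.minus_osc.cds, frameshift_codon, base, loop_codons
    )
    return plus, minus, pair


def gen_mutant_pool(
    construct: Construct,
    spectrum: Sequence[tuple[IndelEvent, float]],
    n_mutants: int,
    seed: int,
    selectable_only: bool = False,
    max_attempts_factor: int = 1000,
) -> list[tuple[IndelEvent, CodingSequence]]:
    """Draw mutants from a weighted indel spectrum applied to ``construct``.

    With ``selectable_only`` events are rejection-sampled until the outcome is
    frame-restoring, emulating a gain-of-function selection; the empirical
    event frequencies then converge to the spectrum conditioned on
    selectability.
    """
    if n_mutants == 0:
        return []
    if not spectrum:
        raise GenerationError("empty spectrum")
    weights = np.array([w for _, w in spectrum], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise GenerationError("spectrum weights must be non-negative and sum > 0")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    pool: list[tuple[IndelEvent, CodingSequence]] = []
    attempts = 0
    budget = max_attempts_factor * n_mutants
    while len(pool) < n_mutants:
        attempts += 1
        if attempts > budget:
            raise GenerationError(
                f"spectrum produced {len(pool)} selectable mutants in {budget} draws; "
                "zero (or too little) selectable mass?"
            )
        event = spectrum[int(rng.choice(len(spectrum), p=weights))][0]
        mutant = apply_indel(construct, event)
        if selectable_only:
            if classify_outcome(construct, mutant).classification != FUNCTIONAL_RESTORED:
                continue
        pool.append((event, mutant))
    return pool


def gen_luria_delbruck(
    m_true: float,
    n0: int,
    n_final: int,
    n_cultures: int,
    seed: int,
) -> FluctuationDataset:
    """Simulate parallel cultures under discrete-generation growth.

    Each culture doubles from ``n0`` for g = log2(n_final/n0) generations.
    Mutations arise at divisions: the per-culture mutation count is
    Poisson(``m_true``), each mutation lands in a generation with probability
    proportional to the cells born there, and the founded clone doubles for
    the remaining generations. Returned ``n_final`` is n0 * 2**g.
    """
    if m_true <= 0:
        raise GenerationError("m_true must be > 0")
    if not (n_final > n0 >= 1):
        raise GenerationError("need n_final > n0 >= 1")
    if n_cultures < 1:
        raise GenerationError("need >= 1 culture")
    g = max(1, math.ceil(math.log2(n_final / n0)))
    rng = np.random.default_rng(seed)
    births = np.array([n0 * 2.0**i for i in range(g)])  # cells born in gen i+1
    p = births / births.sum()
    counts: list[int] = []
    for _ in range(n_cultures):
        k = rng.poisson(m_true)
        total = 0
        if k:
            gens = rng.choice(g, size=k, p=p)
            total = int(sum(2 ** (g - 1 - gen) for gen in gens))
        counts.append(total)
    return FluctuationDataset(tuple(counts), float(n0) * 2.0**g)


def gen_spm_series(
    strain_id: str,
    rate_per_cfu_per_day: float,
    n_days: int,
    cfu_plated: float,
    seed: int,
) -> SpmTimeSeries:
    """Poisson daily revertant counts at a constant per-CFU accumulation rate."""
    if rate_per_cfu_per_day < 0 or cfu_plated <= 0 or n_days < 1:
        raise GenerationError("invalid SPM simulation parameters")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate_per_cfu_per_day * cfu_plated, size=n_days)
    return SpmTimeSeries(
        strain_id=strain_id,
        days=tuple(range(1, n_days + 1)),
        new_revertants=tuple(int(c) for c in counts),
        cfu_plated=cfu_plated,
    )


@dataclasses.dataclass(frozen=True)
class TaxonSpec:
    label: str  # phylum-style label
    n_sequences: int
    loop_length_dist: Mapping[int, float]  # loop length -> probability
    domain: str = "Bacteria"


def gen_alignment(
    taxa: Sequence[TaxonSpec],
    n_columns: int,
    loop_span: tuple[int, int],
    seed: int,
    conserved_columns: Mapping[int, tuple[str, float]] | None = None,
    anchor_residue: str = "K",
) -> tuple[ProteinAlignment, dict[str, tuple[str, str]]]:
    """Toy protein alignment with planted conservation and loop lengths.

    The loop spans ``loop_span`` columns (1-based, inclusive); both anchor
    columns carry ``anchor_residue`` in every row. Each row's loop length L
    (anchors included) is drawn from its taxon's distribution and realized as
    L-2 residues at the left of the interior followed by gaps.
    ``conserved_columns`` plants a consensus residue at a stated identity
    fraction; it must not intersect the loop interior.
    """
    start_col, end_col = loop_span
    interior = end_col - start_col - 1
    if not 1 <= start_col < end_col <= n_columns:
        raise GenerationError("loop span outside alignment")
    conserved_columns = dict(conserved_columns or {})
    for col in conserved_columns:
        if start_col <= col <= end_col:
            raise GenerationError(f"conserved column {col} intersects the loop span")
    for spec in taxa:
        if abs(sum(spec.loop_length_dist.values()) - 1.0) > 1e-9:
            raise GenerationError(f"taxon {spec.label}: loop distribution must sum to 1")
        if max(spec.loop_length_dist) - 2 > interior:
            raise GenerationError(
                f"taxon {spec.label}: loop length {max(spec.loop_length_dist)} "
                f"exceeds span capacity {interior + 2}"
            )
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    rows: list[tuple[str, str]] = []
    taxon_map: dict[str, tuple[str, str]] = {}
    for spec in taxa:
        lengths = list(spec.loop_length_dist)
        probs = np.array([spec.loop_length_dist[l] for l in lengths])
        for i in range(spec.n_sequences):
            seq_id = f"{spec.label}_{i + 1:03d}"
            chars = list(rng.choice(aa, size=n_columns))
            for col, (residue, ident) in conserved_columns.items():
                if rng.random() < ident:
                    chars[col - 1] = residue
                else:
                    others = [a for a in AMINO_ACIDS if a != residue]
                    chars[col - 1] = others[int(rng.integers(len(others)))]
            loop_len = int(lengths[int(rng.choice(len(lengths), p=probs))])
            chars[start_col - 1] = anchor_residue
            chars[end_col - 1] = anchor_residue
            n_res = loop_len - 2
            for j in range(interior):
                col = start_col + j  # 0-based index into chars is start_col+j
                if j >= n_res:
                    chars[col] = "-"
            rows.append((seq_id, "".join(chars)))
            taxon_map[seq_id] = (spec.domain, spec.label)
    return ProteinAlignment(tuple(rows), taxon_map), taxon_map
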