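"""Stationary-phase mutagenesis curves and fluctuation-test rate estimation.

Frequency curves normalize the cumulative number of new revertant colonies
per day to the number of CFU initially plated. Mutation rates from
parallel-culture (Luria-Delbruck) designs use the Lea-Coulson method of the
median: the expected mutations per culture m solves

    r_median / m - ln(m) = 1.24

and the per-cell rate is mu = m / N_t with N_t the cells plated per culture.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .sequence_core import OscKitError, read_table

LEA_COULSON_CONSTANT = 1.24
_BRACKET = (1e-6, 1e6)


class EstimationError(OscKitError):
    pass


class FoldChangeUndefinedError(OscKitError):
    pass


@dataclasses.dataclass(frozen=True)
class SpmTimeSeries:
    """Per-day new revertant counts for one strain, plus the CFU plated."""

    strain_id: str
    days: tuple[int, ...]
    new_revertants: tuple[int, ...]
    cfu_plated: float
    viability: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.cfu_plated <= 0:
            raise OscKitError(f"cfu_plated must be > 0, got {self.cfu_plated}")
        if len(self.days) != len(self.new_revertants):
            raise OscKitError("days and new_revertants differ in length")
        if any(d2 <= d1 for d1, d2 in zip(self.days, self.days[1:])):
            raise OscKitError("days must be strictly increasing")
        if any(c < 0 for c in self.new_revertants):
            raise OscKitError("revertant counts must be non-negative")


@dataclasses.dataclass(frozen=True)
class FluctuationDataset:
    """Per-culture mutant counts and the final cell count per culture."""

    mutant_counts: tuple[int, ...]
    n_final: float

    def __post_init__(self) -> None:
        if not self.mutant_counts:
            raise OscKitError("need at least one culture")
        if self.n_final <= 0:
            raise OscKitError("n_final must be > 0")
        if any(c < 0 for c in self.mutant_counts):
            raise OscKitError("mutant counts must be non-negative")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)


@dataclasses.dataclass(frozen=True)
class RateEstimate:
    m: float  # expected mutations per culture
    mu: float  # mutation rate per cell (m / N_t)
    r_median: float


def cumulative_frequency(series: SpmTimeSeries) -> np.ndarray:
    """Cumulative revertants per plated CFU at each scored day."""
    return np.cumsum(series.new_revertants) / series.cfu_plated


def fold_change(a: SpmTimeSeries, b: SpmTimeSeries, day: int | None = None) -> float:
    """Ratio of cumulative frequencies a/b at ``day`` (default: last common day).

    A zero denominator raises :class:`FoldChangeUndefinedError` rather than
    returning infinity.
    """
    if day is None:
        common = set(a.days) & set(b.days)
        if not common:
            raise OscKitError("series share no scored day")
        day = max(common)
    try:
        ia, ib = a.days.index(day), b.days.index(day)
    except ValueError:
        raise OscKitError(f"day {day} not scored in both series") from None
    fa = cumulative_frequency(a)[ia]
    fb = cumulative_frequency(b)[ib]
    if fb == 0:
        raise FoldChangeUndefinedError(
            f"fold change undefined: zero denominator frequency at day {day}"
        )
    return float(fa / fb)


def median_interpolated(counts: Sequence[float]) -> float:
    """Order-statistic median; even n gives the mean of the two central values."""
    if len(counts) == 0:
        raise OscKitError("empty count list")
    return float(np.median(np.asarray(counts, dtype=float)))


def m_to_median(m: float) -> float:
    """Forward relation: the median count implied by m (Lea-Coulson)."""
    if m <= 0:
        raise EstimationError("m must be > 0")
    return m * (LEA_COULSON_CONSTANT + np.log(m))


def solve_m_from_median(r_median: float) -> float:
    """Invert r/m - ln(m) = 1.24 for m by bracketing + Brent's method."""
    if r_median <= 0:
        raise EstimationError(
            "rate below detection for this design (median mutant count is 0)"
        )

    def f(m: float) -> float:
        return r_median / m - np.log(m) - LEA_COULSON_CONSTANT

    lo, hi = _BRACKET
    if f(lo) < 0 or f(hi) > 0:  # pragma: no cover - bracket spans 12 decades
        raise EstimationError(f"median {r_median} outside solvable bracket")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def lea_coulson_median(data: FluctuationDataset) -> RateEstimate:
    """Method-of-the-median mutation-rate estimate for a fluctuation test."""
    r = median_interpolated(data.mutant_counts)
    m = solve_m_from_median(r)
    return RateEstimate(m=m, mu=m / data.n_final, r_median=r)


def jackknife_ci(
    data: FluctuationDataset, alpha: float = 0.05
) -> tuple[float, float]:
    """Leave-one-culture-out normal-approximation CI for mu (labeled extra)."""
    n = data.n_cultures
    if n < 3:
        raise EstimationError("jackknife needs >= 3 cultures")
    estimates = []
    for i in range(n):
        counts = data.mutant_counts[:i] + data.mutant_counts[i + 1 :]
        r = median_interpolated(counts)
        if r <= 0:
            continue
        estimates.append(solve_m_from_median(r) / data.n_final)
    if len(estimates) < 3:
        raise EstimationError("too many zero-median jackknife replicates")
    est = np.asarray(estimates)
    mean = est.mean()
    se = np.sqrt((len(est) - 1) / len(est) * np.sum((est - mean) ** 2))
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    return float(mean - z * se), float(mean + z * se)


def read_spm_tsv(path: str | Path) -> dict[str, SpmTimeSeries]:
    """TSV columns: strain_id, day, new_revertants, cfu_plated[, viability]."""
    df = read_table(path)
    needed = {"strain_id", "day", "new_revertants", "cfu_plated"}
    missing = needed - set(df.columns)
    if missing:
        raise OscKitError(f"{path}: SPM table missing columns {sorted(missing)}")
    out: dict[str, SpmTimeSeries] = {}
    for strain_id, grp in df.groupby("strain_id", sort=False):
        grp = grp.sort_values("day")
        cfu = grp["cfu_plated"].iloc[0]
        viability = (
            tuple(float(v) for v in grp["viability"])
            if "viability" in grp.columns and grp["viability"].notna().all()
            else None
        )
        out[str(strain_id)] = SpmTimeSeries(
            strain_id=str(strain_id),
            days=tuple(int(d) for d in grp["day"]),
            new_revertants=tuple(int(c) for c in grp["new_revertants"]),
            cfu_plated=float(cfu),
            viability=viability,
        )
    return out


def read_fluctuation_tsv(path: str | Path, n_final: float) -> FluctuationDataset:
    """TSV columns: culture_id, mutant_count; N_t supplied by the caller."""
    df = read_table(path)
    if "mutant_count" not in df.columns:
        raise OscKitError(f"{path}: fluctuation table missing 'mutant_count'")
    return FluctuationDataset(
        tuple(int(c) for c in df["mutant_count"]), float(n_final)
    )
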