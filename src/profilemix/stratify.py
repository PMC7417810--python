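"""Profile-stratified descriptive and inferential tables.

Prevalence by year, outcome rates per profile, between-profile odds ratios
(2x2 tables with Woolf confidence intervals, equivalent to a two-level
logistic regression), and yearly stability with small-cell suppression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .mixture import PosteriorAllocation

__all__ = [
    "OddsRatioResult",
    "prevalence_by_year",
    "outcome_rates_by_profile",
    "odds_ratio_from_table",
    "profile_outcome_or",
    "yearly_stability",
    "MIN_CELL_DEFAULT",
]

MIN_CELL_DEFAULT = 10

Z_95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 odds ratio with a Woolf 95% CI and a Wald p-value.

    The table is ``(a, b, c, d)`` = (outcome & group A, no-outcome & group A,
    outcome & group B, no-outcome & group B); OR = (a*d)/(b*c).
    """

    label: str
    oddsratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple[float, float, float, float]
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.oddsratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def odds_ratio_from_table(a, b, c, d, label: str = "") -> OddsRatioResult:
    """Woolf odds ratio for a 2x2 table, Haldane–Anscombe corrected on zeros."""
    cells = [float(a), float(b), float(c), float(d)]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = math.sqrt(1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - Z_95 * se)
    ci_high = math.exp(log_or + Z_95 * se)
    p = 2.0 * norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        label=label,
        oddsratio=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        table=(float(a), float(b), float(c), float(d)),
        corrected=corrected,
    )


def _primaries(allocations: Sequence[PosteriorAllocation]) -> np.ndarray:
    return np.array([al.primary for al in allocations], int)


def prevalence_by_year(
    allocations: Sequence[PosteriorAllocation],
    years: Sequence,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-year profile membership proportions (rows sum to 1).

    Returns a DataFrame indexed by year with an ``n`` column and one
    proportion column per profile.  An empty year stratum yields a zero row.
    """
    if len(allocations) != len(years):
        raise ValueError("allocations and years must have equal length")
    C = len(allocations[0].probs)
    if labels is None:
        labels = [f"LP{i + 1}" for i in range(C)]
    prim = _primaries(allocations)
    years = np.asarray(years)
    rows = []
    for year in sorted(set(years.tolist())):
        sel = prim[years == year]
        n = sel.size
        counts = np.bincount(sel, minlength=C)
        props = counts / n if n else np.zeros(C)
        rows.append({"year": year, "n": n, **dict(zip(labels, props))})
    return pd.DataFrame(rows).set_index("year")


def outcome_rates_by_profile(
    allocations: Sequence[PosteriorAllocation],
    flags: pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-profile proportion of each outcome flag.

    ``flags`` has one boolean column per outcome and one row per case,
    aligned with ``allocations``.
    """
    if len(allocations) != len(flags):
        raise ValueError("allocations and flags must align")
    C = len(allocations[0].probs)
    if labels is None:
        labels = [f"LP{i + 1}" for i in range(C)]
    prim = _primaries(allocations)
    rows = []
    for j in range(C):
        sel = flags.loc[prim == j]
        row = {"profile": labels[j], "n": len(sel)}
        for col in flags.columns:
            row[col] = sel[col].mean() if len(sel) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("profile")


def profile_outcome_or(
    flags: pd.DataFrame,
    allocations: Sequence[PosteriorAllocation],
    outcome: str,
    profile_a: int,
    profile_b: int,
    labels: Sequence[str] | None = None,
) -> OddsRatioResult:
    """Odds of ``outcome`` in primary-profile A relative to primary-profile B."""
    prim = _primaries(allocations)
    y = np.asarray(flags[outcome], bool)
    in_a = prim == profile_a
    in_b = prim == profile_b
    if not in_a.any() or not in_b.any():
        raise ValueError("both profiles must have at least one member")
    a = int((in_a & y).sum())
    b = int((in_a & ~y).sum())
    c = int((in_b & y).sum())
    d = int((in_b & ~y).sum())
    if labels is None:
        labels = [f"LP{i + 1}" for i in range(len(allocations[0].probs))]
    return odds_ratio_from_table(
        a, b, c, d, label=f"{outcome}: {labels[profile_a]} vs {labels[profile_b]}"
    )


def yearly_stability(
    flags: pd.DataFrame,
    allocations: Sequence[PosteriorAllocation],
    years: Sequence,
    outcome: str,
    min_cell: int = MIN_CELL_DEFAULT,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Outcome rate per (year, profile), suppressing strata with n < min_cell.

    Suppressed cells carry ``rate = NaN`` and ``suppressed = True``.
    """
    if not (len(flags) == len(allocations) == len(years)):
        raise ValueError("inputs must align")
    C = len(allocations[0].probs)
    if labels is None:
        labels = [f"LP{i + 1}" for i in range(C)]
    prim = _primaries(allocations)
    years = np.asarray(years)
    y = np.asarray(flags[outcome], bool)
    rows = []
    for year in sorted(set(years.tolist())):
        for j in range(C):
            sel = (years == year) & (prim == j)
            n = int(sel.sum())
            suppressed = n < min_cell
            rows.append(
                {
                    "year": year,
                    "profile": labels[j],
                    "n": n,
                    "rate": float("nan") if suppressed else float(y[sel].mean()),
                    "suppressed": suppressed,
                }
            )
    return pd.DataFrame(rows)
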