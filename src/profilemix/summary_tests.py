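"""Two-sample tests computed from published summary statistics.

Reproduces t tests (pooled or Welch) from group means/SDs/sizes and pooled
two-proportion z tests from counts, as printed in sample-comparison tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm, t as t_dist

__all__ = ["GroupSummary", "PropSummary", "t_from_summary", "z_two_proportions"]

# two-sided p-values are floored here: the exact value is positive even when
# the tail probability underflows double precision
_P_FLOOR = 2.2250738585072014e-308


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class PropSummary:
    """Successes out of n for one group."""

    count: int
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.count <= self.n:
            raise ValueError("count must lie in [0, n]")


def t_from_summary(
    g1: GroupSummary, g2: GroupSummary, method: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t test from summaries; returns ``(t, df, p)``.

    ``pooled`` uses the df-weighted pooled variance with ``n1 + n2 - 2``
    degrees of freedom; ``welch`` uses unpooled variances with the
    Welch–Satterthwaite approximation.
    """
    v1, v2 = g1.sd**2, g2.sd**2
    if method == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    elif method == "welch":
        a, b = v1 / g1.n, v2 / g2.n
        se = math.sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (g1.n - 1) + b**2 / (g2.n - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    t = (g1.mean - g2.mean) / se
    p = max(2.0 * t_dist.sf(abs(t), df), _P_FLOOR)
    return t, float(df), float(p)


def z_two_proportions(p1: PropSummary, p2: PropSummary) -> tuple[float, float]:
    """Pooled two-proportion z test; returns ``(z, p)``."""
    f1, f2 = p1.count / p1.n, p2.count / p2.n
    pooled = (p1.count + p2.count) / (p1.n + p2.n)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / p1.n + 1.0 / p2.n))
    if se == 0.0:
        return 0.0, 1.0
    z = (f1 - f2) / se
    p = max(2.0 * norm.sf(abs(z)), _P_FLOOR)
    return z, float(p)
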