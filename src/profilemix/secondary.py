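"""Secondary-profile refinement tables.

Within a primary profile, outcome rates are broken down by the profile each
case has its second-highest membership probability for; small secondary
strata are excluded from the table body but tallied so totals reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mixture import PosteriorAllocation

__all__ = ["SecondaryTable", "secondary_table", "secondary_flag_split", "MIN_N_DEFAULT"]

MIN_N_DEFAULT = 10


@dataclass(frozen=True)
class SecondaryTable:
    """Per-secondary-profile outcome rates within one primary profile."""

    primary: int
    included: pd.DataFrame  # index: secondary label; columns: n + outcome rates
    excluded: pd.DataFrame  # secondary label, n, reason
    summary: pd.Series  # all-cases row

    def __post_init__(self) -> None:
        total = int(self.included["n"].sum() + self.excluded["n"].sum())
        if total != int(self.summary["n"]):
            raise ValueError("included + excluded n must equal the summary n")


def _labels(C: int, labels: Sequence[str] | None) -> list[str]:
    return list(labels) if labels is not None else [f"LP{i + 1}" for i in range(C)]


def secondary_table(
    allocations: Sequence[PosteriorAllocation],
    flags: pd.DataFrame,
    primary: int,
    outcomes: Sequence[str],
    min_n: int = MIN_N_DEFAULT,
    labels: Sequence[str] | None = None,
) -> SecondaryTable:
    """Outcome rates by secondary profile for cases whose primary is ``primary``."""
    if len(allocations) != len(flags):
        raise ValueError("allocations and flags must align")
    C = len(allocations[0].probs)
    labs = _labels(C, labels)
    prim = np.array([a.primary for a in allocations])
    sec = np.array([-1 if a.secondary is None else a.secondary for a in allocations])
    sel = prim == primary
    if not sel.any():
        raise ValueError("primary profile has no cases")
    sub_sec = sec[sel]
    sub_flags = flags.loc[sel].reset_index(drop=True)

    inc_rows, exc_rows = [], []
    for j in sorted(set(sub_sec.tolist())):
        m = sub_sec == j
        n = int(m.sum())
        if n < min_n:
            exc_rows.append({"secondary": labs[j], "n": n, "reason": f"n < {min_n}"})
            continue
        row = {"secondary": labs[j], "n": n}
        for out in outcomes:
            row[out] = float(sub_flags.loc[m, out].mean())
        inc_rows.append(row)

    included = pd.DataFrame(inc_rows, columns=["secondary", "n", *outcomes])
    included = included.set_index("secondary")
    excluded = pd.DataFrame(exc_rows, columns=["secondary", "n", "reason"]).set_index(
        "secondary"
    )
    summary = {"n": int(sel.sum())}
    for out in outcomes:
        summary[out] = float(sub_flags[out].mean())
    return SecondaryTable(
        primary=primary,
        included=included,
        excluded=excluded,
        summary=pd.Series(summary),
    )


def secondary_flag_split(
    allocations: Sequence[PosteriorAllocation],
    flags: pd.DataFrame,
    flag_profile: int,
    outcome: str,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Outcome rate per primary profile, split on secondary == ``flag_profile``.

    Rows cover every primary profile except ``flag_profile`` itself; the two
    column groups are cases whose secondary profile is / is not the flagged
    profile ("not" pools all other secondaries).
    """
    if len(allocations) != len(flags):
        raise ValueError("allocations and flags must align")
    C = len(allocations[0].probs)
    labs = _labels(C, labels)
    prim = np.array([a.primary for a in allocations])
    sec = np.array([-1 if a.secondary is None else a.secondary for a in allocations])
    y = np.asarray(flags[outcome], bool)
    rows = []
    for j in range(C):
        if j == flag_profile:
            continue
        in_prim = prim == j
        is_flag = in_prim & (sec == flag_profile)
        not_flag = in_prim & (sec != flag_profile)
        rows.append(
            {
                "profile": labs[j],
                "n_not_flag": int(not_flag.sum()),
                "rate_not_flag": float(y[not_flag].mean()) if not_flag.any() else float("nan"),
                "n_flag": int(is_flag.sum()),
                "rate_flag": float(y[is_flag].mean()) if is_flag.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("profile")
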