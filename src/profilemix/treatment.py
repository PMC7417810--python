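"""Episode-level treatment classification and propensity-matched comparisons.

Episodes mixing low- and high-intensity sessions are excluded from intensity
comparisons; a modality comparison requires the last-received modality to
account for a strict majority of sessions within a single-intensity episode.
Matching is 1:1 greedy nearest-neighbour on the probability scale within a
caliper (default 0.001), with replacement, treated cases processed in
descending propensity order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .stratify import OddsRatioResult, odds_ratio_from_table

__all__ = [
    "LI",
    "HI",
    "MIXED",
    "LI_MODALITIES",
    "HI_MODALITIES",
    "EpisodeTreatment",
    "MatchSpec",
    "MatchedCohort",
    "classify_intensity",
    "main_modality",
    "estimate_propensity",
    "match",
    "compare_matched_outcomes",
    "SeparationError",
]

LI = "LI"
HI = "HI"
MIXED = "mixed"

LI_MODALITIES = ("GSH", "cCBT")
HI_MODALITIES = ("CBT", "Counselling", "IPT")


class SeparationError(ValueError):
    """Perfect separation in the propensity model."""


@dataclass(frozen=True)
class EpisodeTreatment:
    """Per-session modality and intensity labels for one episode of care."""

    session_modalities: tuple[str, ...]
    session_intensities: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.session_modalities) != len(self.session_intensities):
            raise ValueError("modalities and intensities must have equal length")
        if not self.session_modalities:
            raise ValueError("episode must contain at least one session")
        for i in self.session_intensities:
            if i not in (LI, HI):
                raise ValueError(f"unknown intensity {i!r}")

    @property
    def n_sessions(self) -> int:
        return len(self.session_modalities)


@dataclass(frozen=True)
class MatchSpec:
    """1:1 matching contract: caliper width and replacement policy."""

    caliper: float = 0.001
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if self.caliper <= 0:
            raise ValueError("caliper must be positive")


@dataclass(frozen=True)
class MatchedCohort:
    """Matched treated/control index pairs with their propensity distance."""

    pairs: tuple[tuple[int, int, float], ...]
    unmatched_treated: tuple[int, ...]
    scores: np.ndarray
    spec: MatchSpec = field(default_factory=MatchSpec)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def loss_fraction(self, n_available: int) -> float:
        """Fraction of available cases absent from the matched sample."""
        used = {t for t, _, _ in self.pairs} | {c for _, c, _ in self.pairs}
        return 1.0 - len(used) / n_available if n_available else 0.0


def classify_intensity(e: EpisodeTreatment) -> str:
    """``LI``/``HI`` when every session shares that intensity, else ``mixed``."""
    kinds = set(e.session_intensities)
    if kinds == {LI}:
        return LI
    if kinds == {HI}:
        return HI
    return MIXED


def main_modality(e: EpisodeTreatment) -> str | None:
    """The episode's main treatment, or None.

    The last session's modality qualifies only if the episode is
    single-intensity and that modality covers a strict majority of sessions.
    """
    if classify_intensity(e) == MIXED:
        return None
    last = e.session_modalities[-1]
    count = sum(m == last for m in e.session_modalities)
    if count * 2 > e.n_sessions:
        return last
    return None


def estimate_propensity(posteriors: np.ndarray, treated: Sequence[bool]) -> np.ndarray:
    """Propensity scores from a logistic regression on membership posteriors.

    The last profile's probability is dropped (the eight probabilities sum to
    one) and an intercept added; returns fitted treatment probabilities.
    """
    P = np.asarray(posteriors, float)
    t = np.asarray(treated, bool)
    if P.ndim != 2 or P.shape[0] != t.shape[0]:
        raise ValueError("posteriors must be (n_cases, n_profiles) aligned to treated")
    if not t.any() or t.all():
        raise ValueError("need at least one treated and one control case")
    Z = P[:, :-1]
    keep = Z.std(axis=0) > 1e-12  # constant columns carry no information
    X = sm.add_constant(Z[:, keep], has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(t.astype(float), X, family=sm.families.Binomial()).fit()
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"perfect separation in propensity model: {exc}") from exc
    fitted = np.asarray(res.predict(X), float)
    eps = 1e-8
    if (fitted[t] > 1 - eps).all() and (fitted[~t] < eps).all():
        raise SeparationError("perfect separation: treatment fully determined by covariates")
    return fitted


def match(
    scores: np.ndarray, treated: Sequence[bool], spec: MatchSpec | None = None
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbour matching within a caliper.

    Treated cases are processed in descending propensity order (ties by
    index); each is paired with the closest control by absolute score
    difference, ties broken by the lower control index, provided the
    distance does not exceed the caliper (boundary inclusive).  With
    replacement a control may serve several treated cases.
    """
    if spec is None:
        spec = MatchSpec()
    scores = np.asarray(scores, float)
    treated = np.asarray(treated, bool)
    if scores.shape != treated.shape:
        raise ValueError("scores and treated must align")
    t_idx = np.nonzero(treated)[0]
    c_idx = np.nonzero(~treated)[0]
    order = t_idx[np.lexsort((t_idx, -scores[t_idx]))]
    pairs: list[tuple[int, int, float]] = []
    unmatched: list[int] = []
    if c_idx.size == 0:
        return MatchedCohort(
            pairs=(), unmatched_treated=tuple(order.tolist()), scores=scores, spec=spec
        )
    c_scores = scores[c_idx]
    available = np.ones(c_idx.size, bool)
    for ti in order:
        if spec.with_replacement:
            dists = np.abs(c_scores - scores[ti])
        else:
            if not available.any():
                unmatched.append(int(ti))
                continue
            dists = np.where(available, np.abs(c_scores - scores[ti]), np.inf)
        k = int(np.argmin(dists))  # first occurrence -> lowest control index
        d = float(dists[k])
        if d <= spec.caliper + 1e-12:  # boundary inclusive, float-safe
            pairs.append((int(ti), int(c_idx[k]), d))
            if not spec.with_replacement:
                available[k] = False
        else:
            unmatched.append(int(ti))
    for t, c, d in pairs:
        assert d <= spec.caliper + 1e-12, "caliper contract violated"
    return MatchedCohort(
        pairs=tuple(pairs),
        unmatched_treated=tuple(unmatched),
        scores=scores,
        spec=spec,
    )


def compare_matched_outcomes(
    matched: MatchedCohort, flags: pd.DataFrame, outcome: str, label: str = ""
) -> OddsRatioResult:
    """Odds of ``outcome`` in the treated arm versus matched controls.

    Controls are counted once per use (matching with replacement can reuse
    them).  Delegates to the Woolf 2x2 estimator.
    """
    if matched.n_pairs == 0:
        raise ValueError("no matched pairs")
    y = np.asarray(flags[outcome], bool)
    t_ids = [t for t, _, _ in matched.pairs]
    c_ids = [c for _, c, _ in matched.pairs]
    a = int(y[t_ids].sum())
    b = len(t_ids) - a
    c = int(y[c_ids].sum())
    d = len(c_ids) - c
    return odds_ratio_from_table(a, b, c, d, label=label or f"{outcome}: treated vs control")
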