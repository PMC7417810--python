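"""Finite-mixture profiling of mixed continuous/binary clinical indicators.

The model is a latent profile model: each of ``C`` profiles carries a weight
``pi``, a univariate normal for every continuous indicator and a Bernoulli
rate for every binary indicator, with indicators independent given the
profile (local independence).  Cases are allocated to profiles by Bayes-rule
posterior membership probabilities; the profile with the highest posterior is
the *primary* profile and the runner-up the *secondary* profile.

Estimation is by expectation-maximisation with multiple restarts; missing
indicator values (at most two per case) are marginalised by dropping their
factors from the class-conditional product, which is exact under local
independence.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "CONTINUOUS",
    "BINARY",
    "VARIANCE_FLOOR",
    "RATE_EPS",
    "MAX_MISSING",
    "IndicatorSchema",
    "ProfileModel",
    "IndicatorVector",
    "PosteriorAllocation",
    "FitResult",
    "default_schema",
    "continuous_density",
    "class_conditional_likelihood",
    "posterior_probabilities",
    "allocate",
    "log_likelihood",
    "fit_em",
    "model_selection",
    "align_labels",
    "cohort_to_arrays",
]

CONTINUOUS = "continuous"
BINARY = "binary"

#: floor applied to component variances (sigma^2) during estimation
VARIANCE_FLOOR = 1e-4
#: Bernoulli rates are clipped to [RATE_EPS, 1 - RATE_EPS]
RATE_EPS = 1e-6
#: a case may miss at most this many of the nine indicators
MAX_MISSING = 2

_LOG_2PI = math.log(2.0 * math.pi)


class MixtureError(ValueError):
    """Invalid parameters or data passed to a mixture operation."""


class OutOfSupportError(MixtureError):
    """Raised when every class-conditional likelihood underflows to zero."""


@dataclass(frozen=True)
class IndicatorSchema:
    """Ordered description of the indicator battery.

    Parameters
    ----------
    names
        Unique indicator identifiers, continuous indicators first by
        convention (not required).
    kinds
        Per-indicator flag, ``"continuous"`` or ``"binary"``.
    ranges
        Closed interval of valid values for every continuous indicator.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise MixtureError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise MixtureError("indicator names must be unique")
        for k in self.kinds:
            if k not in (CONTINUOUS, BINARY):
                raise MixtureError(f"unknown indicator kind {k!r}")
        for name, kind in zip(self.names, self.kinds):
            if kind == CONTINUOUS and name not in self.ranges:
                raise MixtureError(f"continuous indicator {name!r} has no range")

    @property
    def n_indicators(self) -> int:
        return len(self.names)

    @property
    def continuous_idx(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == CONTINUOUS)

    @property
    def binary_idx(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == BINARY)

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.continuous_idx)

    @property
    def binary_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.binary_idx)

    def range_array(self) -> np.ndarray:
        """(n_continuous, 2) array of [low, high] bounds."""
        return np.array([self.ranges[n] for n in self.continuous_names], float)


def default_schema() -> IndicatorSchema:
    """The nine-indicator battery: four continuous scores, five binary flags."""
    return IndicatorSchema(
        names=(
            "phq",
            "gad",
            "wsas",
            "age",
            "phobia",
            "gender",
            "medication",
            "welfare",
            "ethnicity",
        ),
        kinds=(CONTINUOUS,) * 4 + (BINARY,) * 5,
        ranges={
            "phq": (0.0, 27.0),
            "gad": (0.0, 21.0),
            "wsas": (0.0, 40.0),
            "age": (16.0, 95.0),
        },
    )


@dataclass
class ProfileModel:
    """Parameters of a fitted (or generating) latent profile model.

    Attributes
    ----------
    weights
        Length-``C`` mixing proportions, each in (0, 1), summing to one.
    cont_means, cont_sds
        ``C x n_continuous`` normal means / standard deviations.
    bin_rates
        ``C x n_binary`` Bernoulli success rates in (0, 1).
    schema
        The indicator battery the parameter matrices are aligned to.
    labels
        Length-``C`` profile names (default ``LP1..LPC``).
    """

    weights: np.ndarray
    cont_means: np.ndarray
    cont_sds: np.ndarray
    bin_rates: np.ndarray
    schema: IndicatorSchema = field(default_factory=default_schema)
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.cont_means = np.atleast_2d(np.asarray(self.cont_means, float))
        self.cont_sds = np.atleast_2d(np.asarray(self.cont_sds, float))
        self.bin_rates = np.atleast_2d(np.asarray(self.bin_rates, float))
        C = self.n_profiles
        n_cont = len(self.schema.continuous_idx)
        n_bin = len(self.schema.binary_idx)
        if self.cont_means.shape != (C, n_cont) or self.cont_sds.shape != (C, n_cont):
            raise MixtureError("continuous parameter matrices have wrong shape")
        if self.bin_rates.shape != (C, n_bin):
            raise MixtureError("binary rate matrix has wrong shape")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise MixtureError("profile weights must sum to 1")
        if np.any(self.weights <= 0.0) or np.any(self.weights >= 1.0):
            if C > 1 or not np.allclose(self.weights, 1.0):
                raise MixtureError("profile weights must lie in (0, 1)")
        if np.any(self.cont_sds < math.sqrt(VARIANCE_FLOOR) - 1e-15):
            raise MixtureError("standard deviations below variance floor")
        if np.any(self.bin_rates < RATE_EPS) or np.any(self.bin_rates > 1 - RATE_EPS):
            raise MixtureError("binary rates outside [1e-6, 1 - 1e-6]")
        if self.labels is None:
            self.labels = tuple(f"LP{i + 1}" for i in range(C))
        else:
            self.labels = tuple(self.labels)
            if len(self.labels) != C:
                raise MixtureError("labels length must equal number of profiles")

    @property
    def n_profiles(self) -> int:
        return int(self.weights.shape[0])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": {
                "names": list(self.schema.names),
                "kinds": list(self.schema.kinds),
                "ranges": {k: list(v) for k, v in self.schema.ranges.items()},
            },
            "labels": list(self.labels),
            "weights": self.weights.tolist(),
            "cont_means": self.cont_means.tolist(),
            "cont_sds": self.cont_sds.tolist(),
            "bin_rates": self.bin_rates.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProfileModel":
        schema = IndicatorSchema(
            names=tuple(d["schema"]["names"]),
            kinds=tuple(d["schema"]["kinds"]),
            ranges={k: tuple(v) for k, v in d["schema"]["ranges"].items()},
        )
        return cls(
            weights=np.array(d["weights"], float),
            cont_means=np.array(d["cont_means"], float),
            cont_sds=np.array(d["cont_sds"], float),
            bin_rates=np.array(d["bin_rates"], float),
            schema=schema,
            labels=tuple(d["labels"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ProfileModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def permuted(self, order: Sequence[int]) -> "ProfileModel":
        """Return a copy with profiles reordered by ``order``."""
        order = list(order)
        if sorted(order) != list(range(self.n_profiles)):
            raise MixtureError("order must be a permutation of profile indices")
        return ProfileModel(
            weights=self.weights[order],
            cont_means=self.cont_means[order],
            cont_sds=self.cont_sds[order],
            bin_rates=self.bin_rates[order],
            schema=self.schema,
            labels=tuple(self.labels[i] for i in order),
        )


@dataclass(frozen=True)
class IndicatorVector:
    """One case's indicator values plus an observation mask.

    ``values`` is aligned to the schema; unobserved entries are ignored
    (conventionally ``nan``).  At most :data:`MAX_MISSING` indicators may be
    unobserved.
    """

    values: tuple[float, ...]
    observed: tuple[bool, ...]

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "IndicatorVector":
        vals = [float("nan") if v is None else float(v) for v in values]
        obs = tuple(not math.isnan(v) for v in vals)
        return cls(values=tuple(vals), observed=obs)

    def n_missing(self) -> int:
        return sum(not o for o in self.observed)

    def validate(self, schema: IndicatorSchema) -> None:
        if len(self.values) != schema.n_indicators:
            raise MixtureError("indicator vector length does not match schema")
        if self.n_missing() > MAX_MISSING:
            raise MixtureError(
                f"more than {MAX_MISSING} indicators missing ({self.n_missing()})"
            )
        for i, (v, o) in enumerate(zip(self.values, self.observed)):
            if not o:
                continue
            name, kind = schema.names[i], schema.kinds[i]
            if kind == CONTINUOUS:
                lo, hi = schema.ranges[name]
                if not lo <= v <= hi:
                    raise MixtureError(f"{name}={v} outside range [{lo}, {hi}]")
            else:
                if v not in (0.0, 1.0):
                    raise MixtureError(f"binary indicator {name}={v} not in {{0,1}}")


@dataclass(frozen=True)
class PosteriorAllocation:
    """Posterior membership probabilities with primary/secondary profiles."""

    probs: np.ndarray
    primary: int
    secondary: int | None
    max_prob: float

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "PosteriorAllocation":
        probs = np.asarray(probs, float)
        primary = int(np.argmax(probs))  # ties -> lowest index
        secondary = None
        if probs.shape[0] >= 2:
            rest = probs.copy()
            rest[primary] = -np.inf
            secondary = int(np.argmax(rest))
        return cls(
            probs=probs,
            primary=primary,
            secondary=secondary,
            max_prob=float(probs[primary]),
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of one EM estimation (best restart)."""

    model: ProfileModel
    log_likelihood: float
    trace: tuple[float, ...]
    n_iter: int
    converged: bool
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# densities and likelihoods
# ---------------------------------------------------------------------------

def continuous_density(x, mu, sigma):
    """Univariate normal density ``N(mu, sigma^2)`` evaluated at ``x``."""
    sigma = np.asarray(sigma, float)
    if np.any(sigma <= 0):
        raise MixtureError("sigma must be strictly positive")
    x = np.asarray(x, float)
    mu = np.asarray(mu, float)
    z = (x - mu) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return float(out) if out.ndim == 0 else out


def cohort_to_arrays(
    cohort: Sequence[IndicatorVector], schema: IndicatorSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into a values matrix and observation mask.

    Unobserved cells hold ``nan`` in the values matrix and ``False`` in the
    mask.
    """
    n = len(cohort)
    X = np.full((n, schema.n_indicators), np.nan)
    M = np.zeros((n, schema.n_indicators), bool)
    for r, v in enumerate(cohort):
        if len(v.values) != schema.n_indicators:
            raise MixtureError(f"case {r}: wrong indicator vector length")
        X[r] = v.values
        M[r] = v.observed
    return X, M


def _log_component_matrix(X: np.ndarray, M: np.ndarray, model: ProfileModel) -> np.ndarray:
    """n x C matrix of log class-conditional likelihoods, missing marginalised."""
    schema = model.schema
    ci = list(schema.continuous_idx)
    bi = list(schema.binary_idx)
    Xc, Mc = X[:, ci], M[:, ci]
    Xb, Mb = X[:, bi], M[:, bi]
    Xc = np.where(Mc, Xc, 0.0)
    Xb = np.where(Mb, Xb, 0.0)

    mu = model.cont_means[None, :, :]  # 1 x C x n_cont
    sd = model.cont_sds[None, :, :]
    z = (Xc[:, None, :] - mu) / sd
    with np.errstate(over="ignore"):  # extreme outliers underflow to -inf
        log_cont = -0.5 * (_LOG_2PI + z * z) - np.log(sd)
    log_cont = np.where(Mc[:, None, :], log_cont, 0.0).sum(axis=2)

    th = model.bin_rates[None, :, :]
    log_bin = Xb[:, None, :] * np.log(th) + (1.0 - Xb[:, None, :]) * np.log1p(-th)
    log_bin = np.where(Mb[:, None, :], log_bin, 0.0).sum(axis=2)
    return log_cont + log_bin


def class_conditional_likelihood(
    v: IndicatorVector, model: ProfileModel, j: int
) -> float:
    """P(Y = y | X = j): product of per-indicator factors for profile ``j``.

    Unobserved indicators contribute no factor (exact marginalisation under
    local independence).
    """
    if not 0 <= j < model.n_profiles:
        raise MixtureError(f"profile index {j} out of range")
    if v.n_missing() == len(v.values):
        raise MixtureError("all indicators missing")
    X, M = cohort_to_arrays([v], model.schema)
    return float(np.exp(_log_component_matrix(X, M, model)[0, j]))


def posterior_probabilities(
    v: IndicatorVector, model: ProfileModel
) -> PosteriorAllocation:
    """Bayes-rule posterior membership probabilities for one case."""
    v.validate(model.schema)
    X, M = cohort_to_arrays([v], model.schema)
    return _allocate_arrays(X, M, model)[0]


def _allocate_arrays(
    X: np.ndarray, M: np.ndarray, model: ProfileModel
) -> list[PosteriorAllocation]:
    logp = _log_component_matrix(X, M, model) + np.log(model.weights)[None, :]
    norm = logsumexp(logp, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        idx = int(np.nonzero(bad)[0][0])
        raise OutOfSupportError(
            f"case {idx}: all class-conditional likelihoods are numerically zero"
        )
    post = np.exp(logp - norm[:, None])
    return [PosteriorAllocation.from_probs(row) for row in post]


def allocate(
    cohort: Sequence[IndicatorVector], model: ProfileModel
) -> list[PosteriorAllocation]:
    """Posterior allocation for every case, order preserving."""
    if len(cohort) == 0:
        raise MixtureError("empty cohort")
    for i, v in enumerate(cohort):
        try:
            v.validate(model.schema)
        except MixtureError as exc:
            raise MixtureError(f"case {i}: {exc}") from exc
    X, M = cohort_to_arrays(cohort, model.schema)
    return _allocate_arrays(X, M, model)


def log_likelihood(cohort: Sequence[IndicatorVector], model: ProfileModel) -> float:
    """Total observed-data log-likelihood of the cohort under the model."""
    X, M = cohort_to_arrays(cohort, model.schema)
    return _log_likelihood_arrays(X, M, model)


def _log_likelihood_arrays(X: np.ndarray, M: np.ndarray, model: ProfileModel) -> float:
    logp = _log_component_matrix(X, M, model) + np.log(model.weights)[None, :]
    return float(logsumexp(logp, axis=1).sum())


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _m_step(
    X: np.ndarray, M: np.ndarray, resp: np.ndarray, schema: IndicatorSchema
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    ci = list(schema.continuous_idx)
    bi = list(schema.binary_idx)
    weights = resp.mean(axis=0)
    weights = np.clip(weights, 1e-12, None)
    weights = weights / weights.sum()

    Xc = np.where(M[:, ci], X[:, ci], 0.0)
    Wc = resp[:, :, None] * M[:, None, ci]  # n x C x n_cont
    denom_c = Wc.sum(axis=0)  # C x n_cont
    denom_c = np.clip(denom_c, 1e-12, None)
    means = (Wc * Xc[:, None, :]).sum(axis=0) / denom_c
    var = (Wc * (Xc[:, None, :] - means[None, :, :]) ** 2).sum(axis=0) / denom_c
    var = np.clip(var, VARIANCE_FLOOR, None)
    sds = np.sqrt(var)

    Xb = np.where(M[:, bi], X[:, bi], 0.0)
    Wb = resp[:, :, None] * M[:, None, bi]
    denom_b = np.clip(Wb.sum(axis=0), 1e-12, None)
    rates = (Wb * Xb[:, None, :]).sum(axis=0) / denom_b
    rates = np.clip(rates, RATE_EPS, 1.0 - RATE_EPS)
    return weights, means, sds, rates


def _init_responsibilities(
    X: np.ndarray, M: np.ndarray, C: int, schema: IndicatorSchema, rng: np.random.Generator
) -> np.ndarray:
    """K-means-style hard partition of the continuous block, softened."""
    n = X.shape[0]
    if C == 1:
        return np.ones((n, 1))
    ci = list(schema.continuous_idx)
    Xc = X[:, ci].copy()
    Mc = M[:, ci]
    col_mean = np.nanmean(np.where(Mc, Xc, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    Xc = np.where(Mc, Xc, col_mean[None, :])
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xc - Xc.mean(axis=0)) / sd
    km = KMeans(
        n_clusters=C,
        n_init=1,
        random_state=int(rng.integers(0, 2**31 - 1)),
    ).fit(Z)
    resp = np.full((n, C), 0.1 / C)
    resp[np.arange(n), km.labels_] += 0.9
    resp *= rng.uniform(0.8, 1.2, size=resp.shape)
    resp /= resp.sum(axis=1, keepdims=True)
    return resp


def fit_em(
    cohort,
    C: int,
    seed: int = 0,
    n_starts: int = 20,
    tol: float = 1e-7,
    max_iter: int = 500,
    schema: IndicatorSchema | None = None,
) -> FitResult:
    """Fit a ``C``-profile model by EM with multiple restarts.

    ``cohort`` may be a sequence of :class:`IndicatorVector` or a pre-built
    ``(values, mask)`` array pair.  The best-log-likelihood restart is
    returned; within each restart the observed-data log-likelihood is
    non-decreasing by construction.
    """
    if isinstance(cohort, tuple) and len(cohort) == 2:
        X, M = np.asarray(cohort[0], float), np.asarray(cohort[1], bool)
        if schema is None:
            schema = default_schema()
    else:
        if schema is None:
            schema = default_schema()
        X, M = cohort_to_arrays(cohort, schema)
    n = X.shape[0]
    if C < 1:
        raise MixtureError("C must be at least 1")
    if n < 10 * C:
        raise MixtureError(f"cohort of {n} too small for C={C} (need >= {10 * C})")
    key = np.where(M, X, np.nan)
    n_distinct = len({tuple(row) for row in key.tolist()})
    if C > n_distinct:
        raise MixtureError(f"C={C} exceeds the {n_distinct} distinct cases")

    fit_warnings: list[str] = []
    ci = list(schema.continuous_idx)
    for k, i in enumerate(ci):
        obs = X[M[:, i], i]
        if obs.size and np.all(obs == obs[0]):
            msg = (
                f"continuous indicator {schema.continuous_names[k]!r} is constant; "
                "variance floored"
            )
            fit_warnings.append(msg)
            warnings.warn(msg)

    rng = np.random.default_rng(seed)
    n_starts = 1 if C == 1 else max(1, n_starts)
    best: FitResult | None = None
    for _ in range(n_starts):
        resp = _init_responsibilities(X, M, C, schema, rng)
        weights, means, sds, rates = _m_step(X, M, resp, schema)
        model = ProfileModel(weights, means, sds, rates, schema=schema)
        trace: list[float] = []
        converged = False
        for _it in range(max_iter):
            logp = _log_component_matrix(X, M, model) + np.log(model.weights)[None, :]
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logp - norm[:, None])
            weights, means, sds, rates = _m_step(X, M, resp, schema)
            model = ProfileModel(weights, means, sds, rates, schema=schema)
            if len(trace) >= 2:
                prev = trace[-2]
                if abs(ll - prev) <= tol * max(1.0, abs(prev)):
                    converged = True
                    break
        final_ll = _log_likelihood_arrays(X, M, model)
        trace.append(final_ll)
        result = FitResult(
            model=model,
            log_likelihood=final_ll,
            trace=tuple(trace),
            n_iter=len(trace) - 1,
            converged=converged,
            warnings=tuple(fit_warnings),
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


def n_parameters(C: int, n_cont: int, n_bin: int) -> int:
    """Free-parameter count: (C-1) weights + C*(2*n_cont + n_bin)."""
    return (C - 1) + C * (2 * n_cont + n_bin)


def relative_entropy(post: np.ndarray) -> float:
    """Classification-certainty index: 1 - sum(-p log p) / (n log C)."""
    n, C = post.shape
    if C == 1:
        return 1.0
    p = np.clip(post, 1e-300, 1.0)
    ent = float(-(p * np.log(p)).sum())
    return 1.0 - ent / (n * math.log(C))


def model_selection(cohort, C_range, seed: int = 0, schema=None, **em_kwargs):
    """Fit statistics (log-likelihood, AIC, BIC, entropy) per candidate ``C``.

    Returns a pandas DataFrame with one row per value in ``C_range``.
    """
    import pandas as pd

    C_range = list(C_range)
    if not C_range:
        raise MixtureError("C_range must be non-empty")
    if isinstance(cohort, tuple):
        X, M = np.asarray(cohort[0], float), np.asarray(cohort[1], bool)
        sch = schema or default_schema()
    else:
        sch = schema or default_schema()
        X, M = cohort_to_arrays(cohort, sch)
    n = X.shape[0]
    n_cont, n_bin = len(sch.continuous_idx), len(sch.binary_idx)
    rows = []
    for C in C_range:
        fit = fit_em((X, M), C, seed=seed, schema=sch, **em_kwargs)
        k = n_parameters(C, n_cont, n_bin)
        ll = fit.log_likelihood
        logp = _log_component_matrix(X, M, fit.model) + np.log(fit.model.weights)
        post = np.exp(logp - logsumexp(logp, axis=1)[:, None])
        rows.append(
            {
                "C": C,
                "log_likelihood": ll,
                "n_params": k,
                "aic": -2.0 * ll + 2.0 * k,
                "bic": -2.0 * ll + k * math.log(n),
                "entropy": relative_entropy(post),
            }
        )
    return pd.DataFrame(rows)


def align_labels(fitted: ProfileModel, reference: ProfileModel) -> ProfileModel:
    """Permute ``fitted`` profiles to best match ``reference``.

    The permutation minimises the total squared distance between
    continuous-mean rows (optimal linear assignment).
    """
    if fitted.n_profiles != reference.n_profiles:
        raise MixtureError("models have different numbers of profiles")
    if fitted.schema.names != reference.schema.names:
        raise MixtureError("models have different schemas")
    diff = fitted.cont_means[:, None, :] - reference.cont_means[None, :, :]
    cost = (diff**2).sum(axis=2)  # fitted j x reference k
    row, col = linear_sum_assignment(cost)
    order = row[np.argsort(col)]  # position k <- fitted row assigned to ref k
    return fitted.permuted(order)


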