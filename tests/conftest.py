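import numpy as np
import pytest

import profilemix as pm
from profilemix.mixture import IndicatorSchema, ProfileModel
from profilemix.outcomes import episode_flags, flags_to_frame


@pytest.fixture(scope="session")
def preset():
    return pm.default_preset()


@pytest.fixture(scope="session")
def cohort50k(preset):
    """Full synthetic cohort used by several calibration checks."""
    return pm.generate_cohort(preset, n=50_000, seed=2)


@pytest.fixture(scope="session")
def included50k(cohort50k):
    included, tally = pm.apply_inclusion(cohort50k)
    return included, tally


@pytest.fixture(scope="session")
def allocations50k(preset, included50k):
    included, _ = included50k
    return pm.allocate([r.indicators for r in included], preset.model)


@pytest.fixture(scope="session")
def flags50k(included50k):
    included, _ = included50k
    return flags_to_frame([episode_flags(r.scores) for r in included])


def make_binary_schema(k: int) -> IndicatorSchema:
    return IndicatorSchema(
        names=tuple(f"b{i}" for i in range(k)),
        kinds=("binary",) * k,
    )


def make_binary_model(weights, rates) -> ProfileModel:
    rates = np.atleast_2d(np.asarray(rates, float))
    C, k = rates.shape
    return ProfileModel(
        weights=np.asarray(weights, float),
        cont_means=np.zeros((C, 0)),
        cont_sds=np.zeros((C, 0)),
        bin_rates=rates,
        schema=make_binary_schema(k),
    )


def random_model(rng, C=3, schema=None) -> ProfileModel:
    schema = schema or pm.default_schema()
    n_cont = len(schema.continuous_idx)
    n_bin = len(schema.binary_idx)
    w = rng.dirichlet(np.ones(C) * 5.0)
    bounds = schema.range_array()
    means = rng.uniform(bounds[:, 0], bounds[:, 1], size=(C, n_cont))
    sds = rng.uniform(0.5, 8.0, size=(C, n_cont))
    rates = rng.uniform(0.05, 0.95, size=(C, n_bin))
    return ProfileModel(w, means, sds, rates, schema=schema)


def random_case(rng, schema=None, n_missing=0) -> pm.IndicatorVector:
    schema = schema or pm.default_schema()
    bounds = schema.range_array()
    cont = rng.uniform(bounds[:, 0], bounds[:, 1])
    binv = rng.integers(0, 2, size=len(schema.binary_idx)).astype(float)
    vals = np.concatenate([cont, binv])
    obs = np.ones(len(vals), bool)
    if n_missing:
        drop = rng.choice(len(vals), size=n_missing, replace=False)
        obs[drop] = False
        vals = vals.astype(object)
        for d in drop:
            vals[d] = float("nan")
    return pm.IndicatorVector(values=tuple(float(v) for v in vals), observed=tuple(obs))
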