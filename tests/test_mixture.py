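import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import profilemix as pm
from profilemix.mixture import (
    MAX_MISSING,
    IndicatorSchema,
    MixtureError,
    OutOfSupportError,
    ProfileModel,
    cohort_to_arrays,
    n_parameters,
    relative_entropy,
)

from conftest import make_binary_model, random_case, random_model


# ---------------------------------------------------------------------------
# continuous_density
# ---------------------------------------------------------------------------

def test_density_standard_normal_mode():
    assert pm.continuous_density(0.0, 0.0, 1.0) == pytest.approx(0.3989423, abs=1e-7)


@pytest.mark.parametrize("sigma", [0.3, 1.0, 5.0, 12.0])
def test_density_mode_value(sigma):
    assert pm.continuous_density(3.0, 3.0, sigma) == pytest.approx(
        1.0 / (sigma * math.sqrt(2 * math.pi))
    )


def test_density_matches_scipy_and_integrates():
    mu, sigma = 10.0, 5.0
    assert pm.continuous_density(13.8, mu, sigma) == pytest.approx(
        norm.pdf(13.8, mu, sigma), rel=1e-12
    )
    total, _ = quad(lambda x: pm.continuous_density(x, mu, sigma),
                    mu - 10 * sigma, mu + 10 * sigma)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_density_rejects_nonpositive_sigma():
    with pytest.raises(MixtureError):
        pm.continuous_density(0.0, 0.0, 0.0)
    with pytest.raises(MixtureError):
        pm.continuous_density(0.0, 0.0, -1.0)


# ---------------------------------------------------------------------------
# class_conditional_likelihood
# ---------------------------------------------------------------------------

def test_likelihood_single_bernoulli():
    model = make_binary_model([1.0], [[0.9]])
    v = pm.IndicatorVector.from_values([1.0])
    assert pm.class_conditional_likelihood(v, model, 0) == pytest.approx(0.9)
    v0 = pm.IndicatorVector.from_values([0.0])
    assert pm.class_conditional_likelihood(v0, model, 0) == pytest.approx(0.1)


def test_likelihood_two_halves():
    model = make_binary_model([1.0], [[0.5, 0.5]])
    for y in itertools.product([0.0, 1.0], repeat=2):
        v = pm.IndicatorVector.from_values(list(y))
        assert pm.class_conditional_likelihood(v, model, 0) == pytest.approx(0.25)


def test_likelihood_nine_indicator_product_oracle():
    # straight-line, scalar evaluation of the product
    rng = np.random.default_rng(7)
    model = random_model(rng, C=4)
    v = random_case(rng)
    for j in range(4):
        expected = 1.0
        k_c = k_b = 0
        for i, kind in enumerate(model.schema.kinds):
            y = v.values[i]
            if kind == "continuous":
                mu = model.cont_means[j, k_c]
                sd = model.cont_sds[j, k_c]
                expected *= math.exp(-((y - mu) ** 2) / (2 * sd**2)) / (
                    sd * math.sqrt(2 * math.pi)
                )
                k_c += 1
            else:
                th = model.bin_rates[j, k_b]
                expected *= th if y == 1.0 else 1.0 - th
                k_b += 1
        got = pm.class_conditional_likelihood(v, model, j)
        assert got == pytest.approx(expected, rel=1e-12)


def test_likelihood_marginalises_missing():
    model = make_binary_model([1.0], [[0.9, 0.2]])
    v = pm.IndicatorVector(values=(1.0, float("nan")), observed=(True, False))
    assert pm.class_conditional_likelihood(v, model, 0) == pytest.approx(0.9)


def test_likelihood_all_missing_errors():
    model = make_binary_model([1.0], [[0.9]])
    v = pm.IndicatorVector(values=(float("nan"),), observed=(False,))
    with pytest.raises(MixtureError):
        pm.class_conditional_likelihood(v, model, 0)


def test_likelihood_bad_profile_index():
    model = make_binary_model([1.0], [[0.9]])
    v = pm.IndicatorVector.from_values([1.0])
    with pytest.raises(MixtureError):
        pm.class_conditional_likelihood(v, model, 5)


# ---------------------------------------------------------------------------
# posterior_probabilities
# ---------------------------------------------------------------------------

def test_posterior_single_class():
    model = make_binary_model([1.0], [[0.5]])
    alloc = pm.posterior_probabilities(pm.IndicatorVector.from_values([1.0]), model)
    assert alloc.probs == pytest.approx([1.0])
    assert alloc.primary == 0
    assert alloc.secondary is None


def test_posterior_identical_components_returns_prior():
    model = make_binary_model([0.3, 0.7], [[0.4], [0.4]])
    for y in (0.0, 1.0):
        alloc = pm.posterior_probabilities(pm.IndicatorVector.from_values([y]), model)
        assert alloc.probs == pytest.approx([0.3, 0.7], abs=1e-12)
        assert alloc.primary == 1
        assert alloc.secondary == 0


def test_posterior_two_class_hand_bayes():
    model = make_binary_model([0.5, 0.5], [[0.9], [0.1]])
    alloc = pm.posterior_probabilities(pm.IndicatorVector.from_values([1.0]), model)
    assert alloc.probs == pytest.approx([0.9, 0.1], abs=1e-12)
    assert alloc.primary == 0 and alloc.secondary == 1
    assert alloc.max_prob == pytest.approx(0.9)


def test_posterior_sums_to_one_random_models():
    rng = np.random.default_rng(21)
    for _ in range(50):
        C = int(rng.integers(1, 9))
        model = random_model(rng, C=C)
        v = random_case(rng, n_missing=int(rng.integers(0, MAX_MISSING + 1)))
        alloc = pm.posterior_probabilities(v, model)
        assert abs(alloc.probs.sum() - 1.0) < 1e-9
        assert alloc.primary == int(np.argmax(alloc.probs))
        if C >= 2:
            assert alloc.secondary != alloc.primary


def test_posterior_matches_naive_bayes_oracle():
    # direct, non-stabilised Bayes evaluation
    rng = np.random.default_rng(42)
    for _ in range(30):
        C = int(rng.integers(2, 9))
        model = random_model(rng, C=C)
        v = random_case(rng)
        L = np.array(
            [pm.class_conditional_likelihood(v, model, j) for j in range(C)]
        )
        naive = model.weights * L
        if naive.sum() == 0 or not np.isfinite(naive.sum()):
            continue
        naive = naive / naive.sum()
        alloc = pm.posterior_probabilities(v, model)
        np.testing.assert_allclose(alloc.probs, naive, rtol=1e-10, atol=1e-300)


def test_posterior_out_of_support():
    schema = IndicatorSchema(
        names=("x",), kinds=("continuous",), ranges={"x": (-1e306, 1e306)}
    )
    model = ProfileModel(
        weights=np.array([1.0]),
        cont_means=np.array([[0.0]]),
        cont_sds=np.array([[0.01]]),
        bin_rates=np.zeros((1, 0)),
        schema=schema,
    )
    v = pm.IndicatorVector.from_values([1e300])
    with pytest.raises(OutOfSupportError):
        pm.posterior_probabilities(v, model)


def test_posterior_rejects_excess_missingness():
    rng = np.random.default_rng(3)
    model = random_model(rng, C=2)
    v = random_case(rng, n_missing=3)
    with pytest.raises(MixtureError):
        pm.posterior_probabilities(v, model)


# ---------------------------------------------------------------------------
# allocate
# ---------------------------------------------------------------------------

def test_allocate_trivial_single_case():
    model = make_binary_model([1.0], [[0.5]])
    out = pm.allocate([pm.IndicatorVector.from_values([1.0])], model)
    assert len(out) == 1 and out[0].primary == 0


def test_allocate_equals_per_case_calls():
    rng = np.random.default_rng(5)
    model = random_model(rng, C=4)
    cohort = [random_case(rng) for _ in range(40)]
    batch = pm.allocate(cohort, model)
    for v, alloc in zip(cohort, batch):
        single = pm.posterior_probabilities(v, model)
        np.testing.assert_allclose(alloc.probs, single.probs, rtol=1e-12)
        assert alloc.primary == single.primary
        assert alloc.secondary == single.secondary


def test_allocate_well_separated_two_profiles():
    schema = pm.default_schema()
    model = ProfileModel(
        weights=np.array([0.5, 0.5]),
        cont_means=np.array([[8.0, 6.0, 10.0, 30.0], [20.0, 16.0, 30.0, 60.0]]),
        cont_sds=np.full((2, 4), 2.0),
        bin_rates=np.array([[0.1] * 5, [0.9] * 5]),
        schema=schema,
    )
    cfg = pm.GeneratorConfig(model=model, years={"y": 1.0}, missing_rate=0.0)
    records = pm.generate_baseline(cfg, 2000, seed=9)
    allocations = pm.allocate([r.indicators for r in records], model)
    correct = np.mean(
        [a.primary == r.true_profile for a, r in zip(allocations, records)]
    )
    assert correct >= 0.99


def test_allocate_empty_cohort_errors():
    model = make_binary_model([1.0], [[0.5]])
    with pytest.raises(MixtureError):
        pm.allocate([], model)


def test_allocate_error_reports_case_index():
    model = make_binary_model([1.0], [[0.5, 0.5, 0.5]])
    good = pm.IndicatorVector.from_values([1.0, 0.0, 1.0])
    bad = pm.IndicatorVector.from_values([None, None, None])
    with pytest.raises(MixtureError, match="case 1"):
        pm.allocate([good, bad], model)


def test_allocate_permutation_equivariant():
    rng = np.random.default_rng(17)
    model = random_model(rng, C=5)
    cohort = [random_case(rng) for _ in range(30)]
    perm = [3, 0, 4, 1, 2]
    permuted = model.permuted(perm)
    base = pm.allocate(cohort, model)
    swapped = pm.allocate(cohort, permuted)
    # position k of the permuted model holds old profile perm[k]
    inv = np.argsort(perm)
    for a, b in zip(base, swapped):
        assert b.primary == inv[a.primary]
        assert b.secondary == inv[a.secondary]
        np.testing.assert_allclose(b.probs, a.probs[perm], rtol=1e-12)


# ---------------------------------------------------------------------------
# log_likelihood
# ---------------------------------------------------------------------------

def test_loglik_single_bernoulli():
    model = make_binary_model([1.0], [[0.5]])
    cohort = [pm.IndicatorVector.from_values([1.0])]
    assert pm.log_likelihood(cohort, model) == pytest.approx(math.log(0.5))


def test_loglik_additivity_on_duplication():
    rng = np.random.default_rng(11)
    model = random_model(rng, C=3)
    cohort = [random_case(rng) for _ in range(10)]
    once = pm.log_likelihood(cohort, model)
    twice = pm.log_likelihood(cohort + cohort, model)
    assert twice == pytest.approx(2 * once, rel=1e-12)


def test_loglik_matches_naive_summation():
    rng = np.random.default_rng(13)
    model = random_model(rng, C=4)
    cohort = [random_case(rng) for _ in range(15)]
    naive = 0.0
    for v in cohort:
        s = sum(
            model.weights[j] * pm.class_conditional_likelihood(v, model, j)
            for j in range(4)
        )
        naive += math.log(s)
    assert pm.log_likelihood(cohort, model) == pytest.approx(naive, rel=1e-10)


# ---------------------------------------------------------------------------
# fit_em
# ---------------------------------------------------------------------------

def test_fit_em_single_component_moments():
    rng = np.random.default_rng(23)
    schema = pm.default_schema()
    model = random_model(rng, C=1)
    cfg = pm.GeneratorConfig(model=model, years={"y": 1.0})
    records = pm.generate_baseline(cfg, 300, seed=1)
    X, M = cohort_to_arrays([r.indicators for r in records], schema)
    fit = pm.fit_em((X, M), 1, seed=0)
    np.testing.assert_allclose(fit.model.cont_means[0], X[:, :4].mean(axis=0), rtol=1e-9)
    np.testing.assert_allclose(
        fit.model.cont_sds[0], X[:, :4].std(axis=0), rtol=1e-9
    )  # population-SD convention
    np.testing.assert_allclose(fit.model.bin_rates[0], X[:, 4:].mean(axis=0), rtol=1e-9)
    assert fit.model.weights == pytest.approx([1.0])


def test_fit_em_two_profile_recovery():
    schema = pm.default_schema()
    truth = ProfileModel(
        weights=np.array([0.4, 0.6]),
        cont_means=np.array([[8.0, 6.0, 10.0, 30.0], [20.0, 16.0, 30.0, 60.0]]),
        cont_sds=np.full((2, 4), 2.0),  # separation >= 3 SD everywhere
        bin_rates=np.array([[0.15] * 5, [0.85] * 5]),
        schema=schema,
    )
    cfg = pm.GeneratorConfig(model=truth, years={"y": 1.0})
    records = pm.generate_baseline(cfg, 2000, seed=33)
    X, M = cohort_to_arrays([r.indicators for r in records], schema)
    fit = pm.fit_em((X, M), 2, seed=33, n_starts=5)
    aligned = pm.align_labels(fit.model, truth)
    assert np.abs(aligned.cont_means - truth.cont_means).max() < 0.15
    assert np.abs(aligned.bin_rates - truth.bin_rates).max() < 0.05
    assert np.abs(aligned.weights - truth.weights).max() < 0.03


def test_fit_em_trace_monotone():
    rng = np.random.default_rng(29)
    model = random_model(rng, C=3)
    cfg = pm.GeneratorConfig(model=model, years={"y": 1.0})
    records = pm.generate_baseline(cfg, 400, seed=4)
    X, M = cohort_to_arrays([r.indicators for r in records], pm.default_schema())
    for seed in range(3):
        fit = pm.fit_em((X, M), 3, seed=seed, n_starts=2)
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) >= -1e-8)


def test_fit_em_constant_indicator_warns():
    schema = pm.default_schema()
    X = np.column_stack(
        [
            np.full(50, 12.0),  # constant phq
            np.random.default_rng(0).normal(10, 2, 50),
            np.random.default_rng(1).normal(20, 2, 50),
            np.random.default_rng(2).normal(40, 5, 50),
            np.random.default_rng(3).integers(0, 2, (50, 5)),
        ]
    )
    M = np.ones_like(X, bool)
    with pytest.warns(UserWarning, match="constant"):
        fit = pm.fit_em((X, M), 1, seed=0)
    assert fit.model.cont_sds[0, 0] == pytest.approx(math.sqrt(1e-4))


def test_fit_em_too_small_cohort():
    X = np.zeros((9, 9))
    M = np.ones((9, 9), bool)
    with pytest.raises(MixtureError):
        pm.fit_em((X, M), 1, seed=0)


def test_fit_em_more_profiles_than_distinct_cases():
    base = np.tile(
        np.array([10.0, 8.0, 12.0, 30.0, 1, 0, 1, 0, 1]), (30, 1)
    )
    M = np.ones_like(base, bool)
    with pytest.raises(MixtureError, match="distinct"):
        pm.fit_em((base, M), 2, seed=0)


# ---------------------------------------------------------------------------
# model_selection
# ---------------------------------------------------------------------------

def test_parameter_count_formula():
    assert n_parameters(8, 4, 5) == 111
    assert n_parameters(1, 4, 5) == 13


def test_entropy_single_class_is_one():
    assert relative_entropy(np.ones((10, 1))) == 1.0


def test_model_selection_table(two_profile_cohort):
    X, M = two_profile_cohort
    table = pm.model_selection((X, M), [1, 2, 3], seed=0, n_starts=3)
    assert list(table["C"]) == [1, 2, 3]
    assert table.loc[table["C"] == 1, "entropy"].item() == 1.0
    bics = dict(zip(table["C"], table["bic"]))
    assert bics[2] < bics[1] and bics[2] < bics[3]


@pytest.fixture(scope="module")
def two_profile_cohort():
    schema = pm.default_schema()
    truth = ProfileModel(
        weights=np.array([0.5, 0.5]),
        cont_means=np.array([[8.0, 6.0, 10.0, 30.0], [20.0, 16.0, 30.0, 60.0]]),
        cont_sds=np.full((2, 4), 2.0),
        bin_rates=np.array([[0.1] * 5, [0.9] * 5]),
        schema=schema,
    )
    cfg = pm.GeneratorConfig(model=truth, years={"y": 1.0})
    records = pm.generate_baseline(cfg, 600, seed=8)
    return cohort_to_arrays([r.indicators for r in records], schema)


# ---------------------------------------------------------------------------
# align_labels
# ---------------------------------------------------------------------------

def test_align_identity():
    rng = np.random.default_rng(31)
    model = random_model(rng, C=4)
    aligned = pm.align_labels(model, model)
    np.testing.assert_allclose(aligned.cont_means, model.cont_means)
    assert aligned.labels == model.labels


def test_align_recovers_swap():
    rng = np.random.default_rng(37)
    model = random_model(rng, C=4)
    perm = [2, 0, 3, 1]
    shuffled = model.permuted(perm)
    aligned = pm.align_labels(shuffled, model)
    np.testing.assert_allclose(aligned.cont_means, model.cont_means)
    np.testing.assert_allclose(aligned.weights, model.weights)


@pytest.mark.parametrize("C", [2, 3, 4, 5, 6])
def test_align_cost_matches_exhaustive(C):
    rng = np.random.default_rng(C)
    fitted = random_model(rng, C=C)
    reference = random_model(rng, C=C)
    aligned = pm.align_labels(fitted, reference)
    got = ((aligned.cont_means - reference.cont_means) ** 2).sum()
    diff = fitted.cont_means[:, None, :] - reference.cont_means[None, :, :]
    cost = (diff**2).sum(axis=2)
    best = min(
        sum(cost[p[k], k] for k in range(C))
        for p in itertools.permutations(range(C))
    )
    assert got == pytest.approx(best, rel=1e-12)


def test_align_unequal_C_errors():
    rng = np.random.default_rng(41)
    with pytest.raises(MixtureError):
        pm.align_labels(random_model(rng, C=2), random_model(rng, C=3))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_model_roundtrip(tmp_path):
    rng = np.random.default_rng(43)
    model = random_model(rng, C=5)
    path = tmp_path / "model.json"
    model.save(path)
    back = ProfileModel.load(path)
    np.testing.assert_allclose(back.weights, model.weights, atol=1e-12)
    np.testing.assert_allclose(back.cont_means, model.cont_means, atol=1e-12)
    np.testing.assert_allclose(back.cont_sds, model.cont_sds, atol=1e-12)
    np.testing.assert_allclose(back.bin_rates, model.bin_rates, atol=1e-12)
    assert back.labels == model.labels
    assert back.schema.names == model.schema.names


def test_model_invariant_validation():
    with pytest.raises(MixtureError):
        ProfileModel(
            weights=np.array([0.6, 0.6]),
            cont_means=np.zeros((2, 4)),
            cont_sds=np.ones((2, 4)),
            bin_rates=np.full((2, 5), 0.5),
        )
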