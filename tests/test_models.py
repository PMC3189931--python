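import math

import numpy as np
import pytest
from scipy import integrate

from hiersynth import (
    Dataset,
    McmcSettings,
    PriorSet,
    StudyRecord,
    aggregate_covariate,
    build_model,
    build_model_I,
    build_model_II,
    build_model_III,
    build_model_IV,
    build_two_level,
)
from hiersynth.models import _halfnorm_logpdf


# ---------------------------------------------------------------------------
# independent term-by-term oracle for the joint log density


def _norm(x, mean, var):
    return -0.5 * math.log(2 * math.pi * var) - (x - mean) ** 2 / (2 * var)


def _binom(r, n, p):
    return (
        math.lgamma(n + 1)
        - math.lgamma(r + 1)
        - math.lgamma(n - r + 1)
        + r * math.log(p)
        + (n - r) * math.log(1 - p)
    )


def _halfn(x, var):
    return math.log(2.0) + _norm(x, 0.0, var) if x > 0 else -math.inf


def oracle_density(dataset, params, priors, mean_rule):
    """Brute-force sum of every likelihood and prior term.

    ``mean_rule(study, k, theta, alpha)`` returns the mean of psi_k.
    """
    total = 0.0
    aggs = [0.5 * (s.age_treatment + s.age_control) for s in dataset.studies]
    grand = sum(aggs) / len(aggs)
    for k, s in enumerate(dataset.studies):
        gamma, psi = params["gamma"][k], params["psi"][k]
        p_c = 1.0 / (1.0 + math.exp(-gamma))
        p_t = 1.0 / (1.0 + math.exp(-(gamma + psi)))
        total += _binom(s.r_control, s.n_control, p_c)
        total += _binom(s.r_treatment, s.n_treatment, p_t)
        total += _norm(gamma, 0.0, priors.gamma_prior_variance)
        i = 0 if s.study_type == "randomised" else 1
        mean = mean_rule(s, k, params, grand)
        total += _norm(psi, mean, params["sigma"][i] ** 2)
    for i in range(2):
        total += _norm(params["theta"][i], params["mu"], params["tau"] ** 2)
        total += _halfn(params["sigma"][i], priors.sd_prior_variance)
    total += _halfn(params["tau"], priors.sd_prior_variance)
    total += _norm(params["mu"], priors.mu_prior_mean, priors.mu_prior_variance)
    if "alpha" in params:
        total += _norm(params["alpha"], 0.0, priors.alpha_prior_variance)
    return total


def _theta_of(s, params):
    return params["theta"][0 if s.study_type == "randomised" else 1]


MEAN_RULES = {
    "unadjusted_I": lambda s, k, p, grand: _theta_of(s, p),
    "difference_II": lambda s, k, p, grand: _theta_of(s, p)
    + p["alpha"] * (s.age_treatment - s.age_control),
    "aggregate_III": lambda s, k, p, grand: _theta_of(s, p)
    + p["alpha"] * (0.5 * (s.age_treatment + s.age_control) - grand),
}


def _random_point(rng, n_studies, with_alpha):
    point = {
        "gamma": rng.normal(-3.0, 0.7, n_studies),
        "psi": rng.normal(0.0, 0.5, n_studies),
        "theta": rng.normal(0.0, 0.3, 2),
        "sigma": rng.uniform(0.1, 1.0, 2),
        "mu": rng.normal(0.0, 0.3),
        "tau": rng.uniform(0.1, 1.0),
    }
    if with_alpha:
        point["alpha"] = rng.normal(0.0, 0.2)
    return point


@pytest.mark.parametrize("kind", ["unadjusted_I", "difference_II", "aggregate_III"])
def test_joint_log_density_matches_oracle(kind, small_dataset):
    priors = PriorSet()
    spec = build_model(kind, small_dataset, priors)
    rng = np.random.default_rng(2024)
    for _ in range(5):
        point = _random_point(rng, len(small_dataset), spec.has_alpha)
        expected = oracle_density(small_dataset, point, priors, MEAN_RULES[kind])
        assert spec.log_density(point) == pytest.approx(expected, rel=1e-10)


def test_model_II_with_zero_alpha_equals_model_I(small_dataset):
    spec1 = build_model_I(small_dataset)
    spec2 = build_model_II(small_dataset)
    rng = np.random.default_rng(7)
    for _ in range(5):
        point = _random_point(rng, len(small_dataset), with_alpha=True)
        point["alpha"] = 0.0
        without = {k: v for k, v in point.items() if k != "alpha"}
        # densities differ only by alpha's own prior ordinate at 0
        alpha_prior = _norm(0.0, 0.0, PriorSet().alpha_prior_variance)
        assert spec2.log_density(point) == pytest.approx(
            spec1.log_density(without) + alpha_prior, rel=1e-10
        )


def test_two_level_log_density_matches_oracle(rct_only_dataset):
    priors = PriorSet()
    spec = build_two_level(rct_only_dataset.studies, priors)
    rng = np.random.default_rng(5)
    for _ in range(5):
        J = len(rct_only_dataset)
        point = {
            "gamma": rng.normal(-3.0, 0.7, J),
            "psi": rng.normal(0.0, 0.5, J),
            "mu": rng.normal(0.0, 0.3),
            "sigma": rng.uniform(0.1, 1.0),
        }
        expected = 0.0
        for k, s in enumerate(rct_only_dataset.studies):
            p_c = 1 / (1 + math.exp(-point["gamma"][k]))
            p_t = 1 / (1 + math.exp(-(point["gamma"][k] + point["psi"][k])))
            expected += _binom(s.r_control, s.n_control, p_c)
            expected += _binom(s.r_treatment, s.n_treatment, p_t)
            expected += _norm(point["gamma"][k], 0.0, priors.gamma_prior_variance)
            expected += _norm(point["psi"][k], point["mu"], point["sigma"] ** 2)
        expected += _norm(point["mu"], 0.0, priors.mu_prior_variance)
        expected += _halfn(point["sigma"], priors.sd_prior_variance)
        assert spec.log_density(point) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# structure and wiring


def test_model_I_parameter_count_scenario1(sc1):
    from hiersynth import simulate_dataset

    spec = build_model_I(simulate_dataset(sc1, 0))
    names = spec.parameter_names
    assert sum(n.startswith("gamma") for n in names) == 8
    assert sum(n.startswith("psi") for n in names) == 8
    assert sum(n.startswith("theta") for n in names) == 2
    assert sum(n.startswith("sigma") for n in names) == 2
    assert "mu" in names and "tau" in names and "alpha" not in names
    assert spec.priors.mu_prior_variance == 10.0
    assert math.sqrt(spec.priors.mu_prior_variance) == pytest.approx(math.sqrt(10))


def test_single_type_dataset_rejected(rct_only_dataset):
    with pytest.raises(ValueError, match="each design type"):
        build_model_I(rct_only_dataset)


def test_missing_ages_rejected_with_row(small_dataset):
    frame = small_dataset.to_frame()
    frame.loc[2, "age_treatment"] = np.nan
    ds = Dataset.from_frame(frame)
    with pytest.raises(ValueError, match=r"\[2\]"):
        build_model_II(ds)
    with pytest.raises(ValueError, match=r"\[2\]"):
        build_model_III(ds)


def test_aggregate_covariate_rules(small_dataset):
    s = StudyRecord("randomised", 0, 10, 10, 1, 1, 80.0, 80.0)
    assert aggregate_covariate(s) == 80.0
    s = StudyRecord("nonrandomised", 0, 10, 10, 1, 1, 75.0, 85.0)
    assert aggregate_covariate(s) == 80.0
    spec = build_model_III(small_dataset)
    assert spec.covariate.sum() == pytest.approx(0.0, abs=1e-12)


def test_model_III_collapses_without_covariate_variation():
    studies = [
        StudyRecord("randomised", 0, 100, 100, 5, 4, 78.0, 78.0),
        StudyRecord("randomised", 1, 100, 100, 6, 5, 78.0, 78.0),
        StudyRecord("nonrandomised", 0, 100, 100, 5, 7, 80.0, 76.0),
        StudyRecord("nonrandomised", 1, 100, 100, 4, 6, 82.0, 74.0),
    ]
    spec = build_model_III(Dataset(scenario=None, studies=studies))
    assert np.allclose(spec.covariate, 0.0)
    theta = np.array([0.1, -0.3])
    assert np.allclose(spec.psi_mean(theta, alpha=5.0), theta[spec.type_index])


def test_difference_mean_structure_zero_for_randomised(small_dataset):
    spec = build_model_II(small_dataset)
    theta = np.array([-0.2, -0.2])
    means = spec.psi_mean(theta, alpha=0.7)
    # randomised studies have zero arm difference: mean stays at theta
    assert np.allclose(means[:2], -0.2)
    assert not np.allclose(means[2:], -0.2)


def test_two_level_requires_two_studies(rct_only_dataset):
    with pytest.raises(ValueError, match=">=2"):
        build_two_level(rct_only_dataset.studies[:1])


def test_model_IV_two_stage_wiring(small_dataset, tiny_settings):
    spec = build_model_IV(small_dataset, mcmc_settings=tiny_settings)
    assert spec.kind == "informative_prior_IV"
    # likelihood uses only the randomised studies; no third level
    assert spec.n_studies == 2
    assert not spec.three_level
    names = spec.parameter_names
    assert "tau" not in names and "theta[1]" not in names
    assert spec.mu_prior_mean == pytest.approx(spec.stage1["nrs_pooled_median"])
    assert spec.mu_prior_variance == pytest.approx(
        4.0 * spec.stage1["rct_pooled_variance"]
    )
    unit = build_model_IV(small_dataset, inflation_factor=1.0, mcmc_settings=tiny_settings)
    assert unit.mu_prior_variance == pytest.approx(unit.stage1["rct_pooled_variance"])


def test_model_IV_requires_two_of_each(small_dataset):
    ds = Dataset(scenario=None, studies=small_dataset.studies[:3])
    with pytest.raises(ValueError, match=">=2 studies of each"):
        build_model_IV(ds, mcmc_settings=McmcSettings(burn_in=10, n_keep=10, thin=1))


def test_halfnormal_prior_is_normalised():
    total, _ = integrate.quad(lambda x: math.exp(_halfnorm_logpdf(x, 0.26)), 0, np.inf)
    assert total == pytest.approx(1.0, abs=1e-9)


def test_describe_names_the_structure(small_dataset):
    text = build_model_II(small_dataset).describe()
    assert "difference_II" in text and "alpha" in text and "Binomial" in text
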