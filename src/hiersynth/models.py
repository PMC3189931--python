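"""Joint probability specifications for the four evidence-synthesis models.

All four models share the binomial first level: in study j of design type i,
r_Cij ~ Binomial(n_Cij, p_Cij) and r_Tij ~ Binomial(n_Tij, p_Tij) with
logit(p_Cij) = gamma_ij and logit(p_Tij) = gamma_ij + psi_ij, so psi_ij is
the study log odds ratio.  They differ in the mean structure placed on psi:

* unadjusted (I):          psi_ij ~ N(theta_i, sigma_i^2)
* difference-adjusted (II):psi_ij ~ N(theta_i + alpha*(x_Tij - x_Cij), sigma_i^2)
* aggregate-adjusted (III):psi_ij ~ N(theta_i + alpha*x_ij, sigma_i^2),
  where x_ij is the study-level covariate aggregate (mean of arm means,
  centred at the grand mean across studies)
* informative prior (IV):  a two-level model on the randomised studies only,
  psi_ij ~ N(mu, sigma^2), with mu given an informative prior centred on the
  pooled non-randomised estimate and variance inflated relative to the
  pooled randomised estimate.

Models I-III close with theta_i ~ N(mu, tau^2) and weakly informative
priors: half-normal (pre-truncation variance 0.26) on sigma_i and tau,
N(0, 10) on mu, N(0, 1000) on each gamma_ij and on alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .simulate import Dataset, StudyRecord, RANDOMISED, NONRANDOMISED

__all__ = [
    "PriorSet",
    "ModelSpec",
    "MODEL_KINDS",
    "aggregate_covariate",
    "build_model_I",
    "build_model_II",
    "build_model_III",
    "build_model_IV",
    "build_two_level",
    "two_level_pooled",
    "build_model",
]

MODEL_KINDS = ("unadjusted_I", "difference_II", "aggregate_III", "informative_prior_IV")

# canonical study-type order: index 0 = randomised, 1 = non-randomised
_TYPE_ORDER = (RANDOMISED, NONRANDOMISED)


@dataclass(frozen=True)
class PriorSet:
    """Hyperparameters of the weakly informative priors.

    ``sd_prior_variance`` is the variance of the zero-mean normal that is
    truncated to (0, inf) to form the half-normal prior on the
    random-effects standard deviations (sigma_i and tau).
    """

    sd_prior_variance: float = 0.26
    mu_prior_mean: float = 0.0
    mu_prior_variance: float = 10.0
    gamma_prior_variance: float = 1000.0
    alpha_prior_variance: float = 1000.0

    def __post_init__(self):
        for name in (
            "sd_prior_variance",
            "mu_prior_variance",
            "gamma_prior_variance",
            "alpha_prior_variance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ModelSpec:
    """A fully specified joint distribution ready for MCMC.

    Data enter as flat arrays over studies; ``type_index`` maps each study
    to its design type (0 = randomised, 1 = non-randomised).  For
    three-level specs the free parameters are gamma[j], psi[j], theta[i],
    sigma[i], mu, tau and (models II/III) alpha.  For two-level specs
    (``three_level=False``) they are gamma[j], psi[j], the pooled effect
    ``mu`` and a single ``sigma``.
    """

    kind: str
    r_control: np.ndarray
    n_control: np.ndarray
    r_treatment: np.ndarray
    n_treatment: np.ndarray
    type_index: np.ndarray
    covariate: np.ndarray  # per-study regression value; zeros when has_alpha=False
    priors: PriorSet
    three_level: bool = True
    has_alpha: bool = False
    n_types: int = 2
    # prior on the top-level pooled effect; defaults to the PriorSet values,
    # overridden by model IV's informative prior
    mu_prior_mean: float = 0.0
    mu_prior_variance: float = 10.0
    dataset: Optional[Dataset] = None
    stage1: Optional[dict] = None  # model IV provenance: pooled stage-1 summaries
    inflation_factor: Optional[float] = None

    @property
    def n_studies(self) -> int:
        return int(self.r_control.size)

    @property
    def parameter_names(self) -> list[str]:
        J = self.n_studies
        names = [f"gamma[{j}]" for j in range(J)] + [f"psi[{j}]" for j in range(J)]
        if self.three_level:
            names += [f"theta[{i}]" for i in range(self.n_types)]
            names += [f"sigma[{i}]" for i in range(self.n_types)]
            names += ["mu", "tau"]
        else:
            names += ["mu", "sigma[0]"]
        if self.has_alpha:
            names += ["alpha"]
        return names

    # ------------------------------------------------------------------
    def psi_mean(
        self, theta: np.ndarray, alpha: float = 0.0
    ) -> np.ndarray:
        """Mean of each study's log odds ratio given the upper levels."""
        mean = np.asarray(theta, dtype=float)[self.type_index]
        if self.has_alpha:
            mean = mean + alpha * self.covariate
        return mean

    def log_density(self, params: dict) -> float:
        """Joint log density (likelihood + priors) at a parameter point.

        ``params`` holds arrays ``gamma`` (J,), ``psi`` (J,), and, for
        three-level specs, ``theta`` (n_types,), ``sigma`` (n_types,),
        scalars ``mu``, ``tau``; two-level specs use scalar ``mu`` and
        ``sigma``; models with a covariate coefficient add scalar
        ``alpha``.  Used for audit and oracle testing; the sampler works
        from the same factorisation via its conditional updates.
        """
        p = self.priors
        gamma = np.asarray(params["gamma"], dtype=float)
        psi = np.asarray(params["psi"], dtype=float)
        alpha = float(params.get("alpha", 0.0)) if self.has_alpha else 0.0

        logp_c = -np.logaddexp(0.0, -gamma)  # log expit(gamma)
        log1mp_c = -np.logaddexp(0.0, gamma)
        eta_t = gamma + psi
        logp_t = -np.logaddexp(0.0, -eta_t)
        log1mp_t = -np.logaddexp(0.0, eta_t)

        ll = float(
            np.sum(
                _log_binom_coeff(self.n_control, self.r_control)
                + self.r_control * logp_c
                + (self.n_control - self.r_control) * log1mp_c
                + _log_binom_coeff(self.n_treatment, self.r_treatment)
                + self.r_treatment * logp_t
                + (self.n_treatment - self.r_treatment) * log1mp_t
            )
        )

        lp = float(np.sum(_norm_logpdf(gamma, 0.0, p.gamma_prior_variance)))
        if self.has_alpha:
            lp += _norm_logpdf(alpha, 0.0, p.alpha_prior_variance)

        if self.three_level:
            theta = np.asarray(params["theta"], dtype=float)
            sigma = np.asarray(params["sigma"], dtype=float)
            mu = float(params["mu"])
            tau = float(params["tau"])
            if np.any(sigma <= 0) or tau <= 0:
                return -np.inf
            mean = self.psi_mean(theta, alpha)
            var = (sigma**2)[self.type_index]
            lp += float(np.sum(_norm_logpdf(psi, mean, var)))
            lp += float(np.sum(_norm_logpdf(theta, mu, tau**2)))
            lp += _norm_logpdf(mu, self.mu_prior_mean, self.mu_prior_variance)
            lp += float(np.sum(_halfnorm_logpdf(sigma, p.sd_prior_variance)))
            lp += _halfnorm_logpdf(tau, p.sd_prior_variance)
        else:
            mu = float(params["mu"])
            sigma = float(np.asarray(params["sigma"]).reshape(()))
            if sigma <= 0:
                return -np.inf
            mean = mu + (alpha * self.covariate if self.has_alpha else 0.0)
            lp += float(np.sum(_norm_logpdf(psi, mean, sigma**2)))
            lp += _norm_logpdf(mu, self.mu_prior_mean, self.mu_prior_variance)
            lp += _halfnorm_logpdf(sigma, p.sd_prior_variance)
        return ll + lp

    def describe(self) -> str:
        """Human-readable audit description of the spec."""
        lines = [
            f"model kind: {self.kind}",
            f"studies: {self.n_studies} "
            f"(types present: {sorted(set(self.type_index.tolist()))})",
            "likelihood: r ~ Binomial(n, p); logit p_C = gamma_j; "
            "logit p_T = gamma_j + psi_j",
            f"gamma_j ~ Normal(0, var={self.priors.gamma_prior_variance})",
        ]
        if self.three_level:
            cov = " + alpha*x_j" if self.has_alpha else ""
            lines += [
                f"psi_j ~ Normal(theta_type(j){cov}, sigma_type(j)^2)",
                "theta_i ~ Normal(mu, tau^2)",
                f"mu ~ Normal({self.mu_prior_mean}, var={self.mu_prior_variance})",
                f"sigma_i, tau ~ HalfNormal(var={self.priors.sd_prior_variance})",
            ]
        else:
            lines += [
                "psi_j ~ Normal(mu, sigma^2)",
                f"mu ~ Normal({self.mu_prior_mean:.6g}, var={self.mu_prior_variance:.6g})",
                f"sigma ~ HalfNormal(var={self.priors.sd_prior_variance})",
            ]
        if self.has_alpha:
            lines.append(
                f"alpha ~ Normal(0, var={self.priors.alpha_prior_variance}); "
                "per-study covariate x_j attached"
            )
        if self.inflation_factor is not None:
            lines.append(f"informative-prior variance inflation factor: {self.inflation_factor}")
        return "\n".join(lines)


def _log_binom_coeff(n, r):
    from scipy.special import gammaln

    n = np.asarray(n, dtype=float)
    r = np.asarray(r, dtype=float)
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def _norm_logpdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _halfnorm_logpdf(x, var):
    # zero-mean normal with variance `var`, truncated to (0, inf)
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0, math.log(2.0) - 0.5 * (np.log(2.0 * np.pi * var) + x**2 / var), -np.inf
    )
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# builders


def _dataset_arrays(dataset: Dataset) -> dict:
    frame = dataset.to_frame()
    type_index = frame["study_type"].map({RANDOMISED: 0, NONRANDOMISED: 1})
    if type_index.isna().any():
        bad = frame.loc[type_index.isna(), "study_type"].unique()
        raise ValueError(f"unknown study types: {list(bad)}")
    return {
        "r_control": frame["r_control"].to_numpy(dtype=np.int64),
        "n_control": frame["n_control"].to_numpy(dtype=np.int64),
        "r_treatment": frame["r_treatment"].to_numpy(dtype=np.int64),
        "n_treatment": frame["n_treatment"].to_numpy(dtype=np.int64),
        "type_index": type_index.to_numpy(dtype=np.int64),
        "ages_t": frame["age_treatment"].to_numpy(dtype=float),
        "ages_c": frame["age_control"].to_numpy(dtype=float),
    }


def _require_both_types(arrays: dict, kind: str) -> None:
    present = set(arrays["type_index"].tolist())
    if present != {0, 1}:
        raise ValueError(
            f"{kind} requires at least one study of each design type "
            "(randomised and non-randomised); the three-level structure is "
            "undefined otherwise"
        )


def _require_ages(arrays: dict, kind: str) -> None:
    bad = np.flatnonzero(np.isnan(arrays["ages_t"]) | np.isnan(arrays["ages_c"]))
    if bad.size:
        raise ValueError(
            f"{kind} needs arm mean ages for every study; missing for study "
            f"row(s) {bad.tolist()}"
        )


def build_model_I(dataset: Dataset, priors: PriorSet | None = None) -> ModelSpec:
    """Three-level hierarchical model, unadjusted for imbalances."""
    priors = priors or PriorSet()
    arrays = _dataset_arrays(dataset)
    _require_both_types(arrays, "model I")
    J = arrays["r_control"].size
    return ModelSpec(
        kind="unadjusted_I",
        r_control=arrays["r_control"],
        n_control=arrays["n_control"],
        r_treatment=arrays["r_treatment"],
        n_treatment=arrays["n_treatment"],
        type_index=arrays["type_index"],
        covariate=np.zeros(J),
        priors=priors,
        three_level=True,
        has_alpha=False,
        mu_prior_mean=priors.mu_prior_mean,
        mu_prior_variance=priors.mu_prior_variance,
        dataset=dataset,
    )


def build_model_II(dataset: Dataset, priors: PriorSet | None = None) -> ModelSpec:
    """Three-level model adjusted for within-study arm differences in the
    covariate: mean psi_ij = theta_i + alpha * (x_Tij - x_Cij), with a
    single alpha shared across all studies of both types."""
    priors = priors or PriorSet()
    arrays = _dataset_arrays(dataset)
    _require_both_types(arrays, "model II")
    _require_ages(arrays, "model II")
    spec = build_model_I(dataset, priors)
    spec.kind = "difference_II"
    spec.has_alpha = True
    spec.covariate = arrays["ages_t"] - arrays["ages_c"]
    return spec


def aggregate_covariate(study: StudyRecord) -> float:
    """Study-level covariate aggregate: unweighted mean of the arm means."""
    return 0.5 * (study.age_treatment + study.age_control)


def build_model_III(dataset: Dataset, priors: PriorSet | None = None) -> ModelSpec:
    """Three-level model with meta-regression on the aggregate covariate.

    The aggregate (mean of arm means) is centred at the grand mean across
    studies before entering the regression, for sampler identifiability;
    centring shifts only the theta_i intercepts, not the pooled contrast.
    """
    priors = priors or PriorSet()
    arrays = _dataset_arrays(dataset)
    _require_both_types(arrays, "model III")
    _require_ages(arrays, "model III")
    spec = build_model_I(dataset, priors)
    spec.kind = "aggregate_III"
    spec.has_alpha = True
    agg = np.array([aggregate_covariate(s) for s in dataset.studies])
    spec.covariate = agg - agg.mean()
    return spec


def build_two_level(
    studies: list[StudyRecord],
    priors: PriorSet | None = None,
    mu_prior_mean: float | None = None,
    mu_prior_variance: float | None = None,
    kind: str = "two_level",
) -> ModelSpec:
    """Simple Bayesian random-effects (two-level) model on one study subset.

    psi_ij ~ N(mu, sigma^2) with mu ~ N(mu_prior_mean, mu_prior_variance)
    and sigma half-normal.
    """
    priors = priors or PriorSet()
    if len(studies) < 2:
        raise ValueError(
            f"two-level pooled model needs >=2 studies; got {len(studies)}"
        )
    dataset = Dataset(scenario=None, studies=list(studies))
    arrays = _dataset_arrays(dataset)
    J = arrays["r_control"].size
    return ModelSpec(
        kind=kind,
        r_control=arrays["r_control"],
        n_control=arrays["n_control"],
        r_treatment=arrays["r_treatment"],
        n_treatment=arrays["n_treatment"],
        type_index=np.zeros(J, dtype=np.int64),
        covariate=np.zeros(J),
        priors=priors,
        three_level=False,
        has_alpha=False,
        n_types=1,
        mu_prior_mean=priors.mu_prior_mean if mu_prior_mean is None else mu_prior_mean,
        mu_prior_variance=(
            priors.mu_prior_variance if mu_prior_variance is None else mu_prior_variance
        ),
        dataset=dataset,
    )


def two_level_pooled(studies, priors=None, mcmc_settings=None):
    """Fit the two-level pooled model to one study subset and return the
    posterior of the pooled effect (reported under both ``mu`` and, as the
    conventional random-effects notation, ``theta``)."""
    from .mcmc import McmcSettings, fit

    spec = build_two_level(studies, priors)
    settings = mcmc_settings or McmcSettings.reduced()
    return fit(spec, settings)


def build_model_IV(
    dataset: Dataset,
    priors: PriorSet | None = None,
    inflation_factor: float = 4.0,
    mcmc_settings=None,
) -> ModelSpec:
    """Informative-prior downweighting of the non-randomised evidence.

    Two-stage construction: (1) fit the two-level pooled model separately
    to the non-randomised studies (keeping the posterior median m_N of the
    pooled effect) and to the randomised studies (keeping the posterior
    variance v_R); (2) return a two-level spec whose likelihood uses ONLY
    the randomised studies, with the pooled effect given the prior
    Normal(m_N, inflation_factor * v_R).  Larger inflation factors
    downweight the non-randomised evidence more.
    """
    from .mcmc import McmcSettings, fit

    priors = priors or PriorSet()
    if inflation_factor <= 0:
        raise ValueError("inflation_factor must be strictly positive")
    rct = dataset.of_type(RANDOMISED)
    nrs = dataset.of_type(NONRANDOMISED)
    if len(rct) < 2 or len(nrs) < 2:
        raise ValueError(
            "model IV needs >=2 studies of each design type; got "
            f"{len(rct)} randomised / {len(nrs)} non-randomised"
        )
    settings = mcmc_settings or McmcSettings.reduced()
    seed = settings.seed if settings.seed is not None else 0
    nrs_fit = fit(build_two_level(nrs, priors), settings.with_seed(seed * 2 + 1))
    rct_fit = fit(build_two_level(rct, priors), settings.with_seed(seed * 2 + 2))
    m_n = nrs_fit.summaries.loc["mu", "median"]
    v_r = rct_fit.summaries.loc["mu", "variance"]

    spec = build_two_level(
        rct,
        priors,
        mu_prior_mean=float(m_n),
        mu_prior_variance=float(inflation_factor * v_r),
        kind="informative_prior_IV",
    )
    spec.dataset = dataset
    spec.inflation_factor = float(inflation_factor)
    spec.stage1 = {
        "nrs_pooled_median": float(m_n),
        "rct_pooled_variance": float(v_r),
        "rct_pooled_median": float(rct_fit.summaries.loc["mu", "median"]),
    }
    return spec


_BUILDERS = {
    "unadjusted_I": build_model_I,
    "difference_II": build_model_II,
    "aggregate_III": build_model_III,
}

_ALIASES = {
    "I": "unadjusted_I",
    "II": "difference_II",
    "III": "aggregate_III",
    "IV": "informative_prior_IV",
    "1": "unadjusted_I",
    "2": "difference_II",
    "3": "aggregate_III",
    "4": "informative_prior_IV",
}


def canonical_kind(kind: str) -> str:
    kind = _ALIASES.get(str(kind).strip(), str(kind).strip())
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
    return kind


def build_model(kind: str, dataset: Dataset, priors=None, **kwargs) -> ModelSpec:
    """Dispatch to the builder for ``kind`` (accepts I/II/III/IV aliases)."""
    kind = canonical_kind(kind)
    if kind == "informative_prior_IV":
        return build_model_IV(dataset, priors, **kwargs)
    return _BUILDERS[kind](dataset, priors)
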