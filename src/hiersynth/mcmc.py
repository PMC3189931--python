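"""MCMC fitting of model specifications.

The sampler is a Metropolis-within-Gibbs scheme tailored to the model
family: the study-type means theta_i, the population mean mu and the
imbalance coefficient alpha have normal full conditionals and are drawn
exactly (Gibbs steps); the study-level log odds gamma_ij and log odds
ratios psi_ij use per-coordinate random-walk Metropolis (their full
conditionals factor across studies, so all studies are updated in one
vectorised accept/reject); the standard deviations sigma_i and tau are
updated by random-walk Metropolis on the log scale with the truncated
normal prior evaluated on the positive domain.  Proposal scales adapt
toward ~44% acceptance during burn-in and are frozen afterwards.

Everything is vectorised over a batch axis, so the two diagnostic chains —
and, in the simulation harness, all replicate datasets of a scenario — are
advanced simultaneously.  Each batch element has its own state, proposals
and acceptance decisions; batching changes speed, not the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelSpec

__all__ = ["McmcSettings", "PosteriorResult", "fit", "fit_many", "psrf", "summarise"]

_TARGET_ACCEPT = 0.44  # optimal-ish for one-dimensional random-walk MH
_ADAPT_WINDOW = 50
_MAX_INIT_RETRIES = 5


@dataclass(frozen=True)
class McmcSettings:
    """Chain layout.  Defaults give the full-fidelity profile: 2 chains,
    50k burn-in, 10k further iterations thinned by 20 (500 retained per
    chain, 1000 total).  ``reduced()`` is the profile used by the test
    suite and the bundled study harness."""

    n_chains: int = 2
    burn_in: int = 50_000
    n_keep: int = 10_000
    thin: int = 20
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.burn_in < 0 or self.n_keep <= 0 or self.thin <= 0:
            raise ValueError("burn_in >= 0, n_keep > 0 and thin > 0 required")
        if self.n_keep % self.thin != 0:
            raise ValueError(
                f"n_keep ({self.n_keep}) must be divisible by thin ({self.thin})"
            )

    @property
    def draws_per_chain(self) -> int:
        return self.n_keep // self.thin

    @classmethod
    def full(cls, seed: Optional[int] = None) -> "McmcSettings":
        return cls(seed=seed)

    @classmethod
    def reduced(cls, seed: Optional[int] = None, burn_in: int = 3000) -> "McmcSettings":
        """Shorter-adaptation profile: same 1000 total retained draws,
        with burn-in sized to this sampler's adaptation needs."""
        return cls(n_chains=2, burn_in=burn_in, n_keep=5000, thin=10, seed=seed)

    def with_seed(self, seed: int) -> "McmcSettings":
        return replace(self, seed=int(seed))


# ----------------------------------------------------------------------
# diagnostics & summaries


def psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor (between/within variance ratio).

    ``chains`` has shape (n_chains, n_draws).  Returns
    sqrt(((n-1)/n * W + B/n) / W) where W is the mean within-chain variance
    and B/n the variance of the chain means.  Identical chains give 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("psrf needs draws from >= 2 chains")
    m, n = chains.shape
    if n < 10:
        raise ValueError("psrf needs >= 10 draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return 1.0
    # the raw estimator can dip marginally below 1 on stationary chains;
    # floor it so the statistic reads as "no excess between-chain variability"
    return float(max(1.0, math.sqrt((n - 1) / n + b_over_n / w)))


def _summary_from_pooled(pooled: np.ndarray) -> dict:
    q = np.percentile(pooled, [2.5, 50.0, 97.5])
    return {
        "median": q[1],
        "mean": float(pooled.mean()),
        "variance": float(pooled.var(ddof=1)),
        "q2.5": q[0],
        "q97.5": q[2],
    }


@dataclass
class PosteriorResult:
    """Thinned posterior draws per chain plus summaries and diagnostics.

    ``draws`` maps each scalar parameter name (e.g. ``mu``, ``theta[1]``,
    ``psi[3]``) to an array of shape (n_chains, draws_per_chain).
    Summaries pool all chains after thinning.
    """

    draws: dict
    settings: McmcSettings
    kind: str = ""

    def __post_init__(self):
        self._summaries: Optional[pd.DataFrame] = None

    @property
    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def pooled(self, parameter: str) -> np.ndarray:
        if parameter not in self.draws:
            raise KeyError(
                f"unknown parameter {parameter!r}; available: {self.parameter_names}"
            )
        return np.asarray(self.draws[parameter]).reshape(-1)

    @property
    def summaries(self) -> pd.DataFrame:
        if self._summaries is None:
            rows = {}
            for name, arr in self.draws.items():
                row = _summary_from_pooled(np.asarray(arr).reshape(-1))
                row["psrf"] = (
                    psrf(arr) if arr.shape[0] >= 2 and arr.shape[1] >= 10 else np.nan
                )
                rows[name] = row
            self._summaries = pd.DataFrame.from_dict(rows, orient="index")
        return self._summaries

    def summarise(self, parameter: str) -> pd.Series:
        self.pooled(parameter)  # raises on unknown name
        return self.summaries.loc[parameter]

    def diagnostics_frame(self) -> pd.DataFrame:
        return self.summaries[["psrf"]].copy()

    def converged(self, parameters: Optional[Sequence[str]] = None, threshold: float = 1.1) -> bool:
        names = list(parameters) if parameters is not None else self.parameter_names
        return bool(all(self.summaries.loc[n, "psrf"] < threshold for n in names))

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws: one row per retained iteration per chain."""
        n_chains = self.settings.n_chains
        k = next(iter(self.draws.values())).shape[1]
        data = {"chain": np.repeat(np.arange(n_chains), k),
                "iteration": np.tile(np.arange(k), n_chains)}
        for name, arr in self.draws.items():
            data[name] = np.asarray(arr).reshape(-1)
        return pd.DataFrame(data)


def summarise(result: PosteriorResult, parameter: str) -> pd.Series:
    """Median / mean / variance / central 95% interval of a parameter,
    pooled over all chains after thinning."""
    return result.summarise(parameter)


# ----------------------------------------------------------------------
# batched state and updates


def _binll(eta, r, n):
    # binomial log likelihood in the log-odds, dropping the binomial coefficient
    return r * eta - n * np.logaddexp(0.0, eta)


class _Batch:
    """Stacked data for B independent sampler states sharing one study layout."""

    def __init__(self, specs: Sequence[ModelSpec], n_chains: int):
        ref = specs[0]
        for s in specs[1:]:
            if (
                s.n_studies != ref.n_studies
                or not np.array_equal(s.type_index, ref.type_index)
                or s.three_level != ref.three_level
                or s.has_alpha != ref.has_alpha
                or s.priors != ref.priors
            ):
                raise ValueError("batched specs must share layout, flags and priors")
        self.specs = list(specs)
        self.n_chains = n_chains
        self.three_level = ref.three_level
        self.has_alpha = ref.has_alpha
        self.priors = ref.priors
        self.type_index = ref.type_index
        self.n_types = ref.n_types if ref.three_level else 1
        self.idx_by_type = [
            np.flatnonzero(ref.type_index == i) for i in range(self.n_types)
        ]
        self.J = ref.n_studies
        self.B = len(specs) * n_chains

        def stack(attr):
            return np.repeat(
                np.stack([np.asarray(getattr(s, attr), dtype=float) for s in specs]),
                n_chains,
                axis=0,
            )

        self.r_c = stack("r_control")
        self.n_c = stack("n_control")
        self.r_t = stack("r_treatment")
        self.n_t = stack("n_treatment")
        self.cov = stack("covariate")
        self.mu_pm = np.repeat(
            np.array([s.mu_prior_mean for s in specs], dtype=float), n_chains
        )
        self.mu_pv = np.repeat(
            np.array([s.mu_prior_variance for s in specs], dtype=float), n_chains
        )


def _initial_state(batch: _Batch, rng: np.random.Generator) -> dict:
    """Empirical-logit initial values (0.5 continuity correction), jittered
    per batch element; SDs start at the half-normal prior median."""
    logit_c = np.log((batch.r_c + 0.5) / (batch.n_c - batch.r_c + 0.5))
    logit_t = np.log((batch.r_t + 0.5) / (batch.n_t - batch.r_t + 0.5))
    sd0 = math.sqrt(batch.priors.sd_prior_variance) * 0.6744897501960817  # HN median
    for attempt in range(_MAX_INIT_RETRIES):
        state = {
            "gamma": logit_c + 0.1 * rng.standard_normal((batch.B, batch.J)),
            "psi": (logit_t - logit_c) + 0.1 * rng.standard_normal((batch.B, batch.J)),
        }
        state["log_sigma"] = math.log(sd0) + 0.1 * rng.standard_normal(
            (batch.B, batch.n_types)
        )
        state["mu"] = 0.1 * rng.standard_normal(batch.B)
        if batch.three_level:
            state["theta"] = 0.1 * rng.standard_normal((batch.B, batch.n_types))
            state["log_tau"] = math.log(sd0) + 0.1 * rng.standard_normal(batch.B)
        if batch.has_alpha:
            state["alpha"] = 0.1 * rng.standard_normal(batch.B)
        ll = _binll(state["gamma"], batch.r_c, batch.n_c) + _binll(
            state["gamma"] + state["psi"], batch.r_t, batch.n_t
        )
        if np.all(np.isfinite(ll)):
            return state
    raise RuntimeError(
        "could not find a finite-density initial state after "
        f"{_MAX_INIT_RETRIES} jittered attempts; check the input counts"
    )


def _psi_mean_var(batch: _Batch, state: dict):
    sigma2 = np.exp(2.0 * state["log_sigma"])
    if batch.three_level:
        mean = state["theta"][:, batch.type_index]
        var = sigma2[:, batch.type_index]
    else:
        mean = state["mu"][:, None] * np.ones((1, batch.J))
        var = sigma2[:, [0] * batch.J]
    if batch.has_alpha:
        mean = mean + state["alpha"][:, None] * batch.cov
    return mean, var


def _step(batch: _Batch, state: dict, steps: dict, accepts: dict, rng) -> None:
    """One full Metropolis-within-Gibbs sweep, in place."""
    pr = batch.priors
    B, J = batch.B, batch.J

    # --- gamma | rest : per-study random-walk MH --------------------------
    gamma, psi = state["gamma"], state["psi"]
    prop = gamma + steps["gamma"] * rng.standard_normal((B, J))
    cur = (
        _binll(gamma, batch.r_c, batch.n_c)
        + _binll(gamma + psi, batch.r_t, batch.n_t)
        - 0.5 * gamma**2 / pr.gamma_prior_variance
    )
    new = (
        _binll(prop, batch.r_c, batch.n_c)
        + _binll(prop + psi, batch.r_t, batch.n_t)
        - 0.5 * prop**2 / pr.gamma_prior_variance
    )
    acc = np.log(rng.random((B, J))) < new - cur
    state["gamma"] = np.where(acc, prop, gamma)
    accepts["gamma"] += acc

    # --- psi | rest : per-study random-walk MH ----------------------------
    gamma = state["gamma"]
    mean, var = _psi_mean_var(batch, state)
    prop = psi + steps["psi"] * rng.standard_normal((B, J))
    cur = _binll(gamma + psi, batch.r_t, batch.n_t) - 0.5 * (psi - mean) ** 2 / var
    new = _binll(gamma + prop, batch.r_t, batch.n_t) - 0.5 * (prop - mean) ** 2 / var
    acc = np.log(rng.random((B, J))) < new - cur
    psi = np.where(acc, prop, psi)
    state["psi"] = psi
    accepts["psi"] += acc

    sigma2 = np.exp(2.0 * state["log_sigma"])
    resid = psi - (state["alpha"][:, None] * batch.cov if batch.has_alpha else 0.0)

    if batch.three_level:
        tau2 = np.exp(2.0 * state["log_tau"])
        # --- theta_i | rest : exact normal draw ---------------------------
        z = rng.standard_normal((B, batch.n_types))
        theta = state["theta"]
        for i, idx in enumerate(batch.idx_by_type):
            prec = idx.size / sigma2[:, i] + 1.0 / tau2
            mean_i = (
                resid[:, idx].sum(axis=1) / sigma2[:, i] + state["mu"] / tau2
            ) / prec
            theta[:, i] = mean_i + z[:, i] / np.sqrt(prec)
        # --- mu | theta, tau : exact normal draw --------------------------
        prec = batch.n_types / tau2 + 1.0 / batch.mu_pv
        mean_mu = (theta.sum(axis=1) / tau2 + batch.mu_pm / batch.mu_pv) / prec
        state["mu"] = mean_mu + rng.standard_normal(B) / np.sqrt(prec)
        level_mean = theta[:, batch.type_index]
    else:
        # --- mu (pooled effect) | psi, sigma : exact normal draw ----------
        prec = J / sigma2[:, 0] + 1.0 / batch.mu_pv
        mean_mu = (resid.sum(axis=1) / sigma2[:, 0] + batch.mu_pm / batch.mu_pv) / prec
        state["mu"] = mean_mu + rng.standard_normal(B) / np.sqrt(prec)
        level_mean = state["mu"][:, None] * np.ones((1, J))

    # --- alpha | rest : exact normal draw ---------------------------------
    if batch.has_alpha:
        w = 1.0 / (
            sigma2[:, batch.type_index] if batch.three_level else sigma2[:, [0] * J]
        )
        prec = (batch.cov**2 * w).sum(axis=1) + 1.0 / pr.alpha_prior_variance
        mean_a = ((psi - level_mean) * batch.cov * w).sum(axis=1) / prec
        state["alpha"] = mean_a + rng.standard_normal(B) / np.sqrt(prec)
        resid = psi - state["alpha"][:, None] * batch.cov

    # --- sigma_i | rest : random-walk MH on log scale ---------------------
    mean, _ = _psi_mean_var(batch, state)
    dev2 = (psi - mean) ** 2
    log_sigma = state["log_sigma"]
    z = rng.standard_normal((B, batch.n_types))
    logu = np.log(rng.random((B, batch.n_types)))
    for i, idx in enumerate(batch.idx_by_type):
        ssr = dev2[:, idx].sum(axis=1)
        cur_ls = log_sigma[:, i]
        prop_ls = cur_ls + steps["log_sigma"][:, i] * z[:, i]

        def target(ls):
            s2 = np.exp(2.0 * ls)
            return (
                -(idx.size - 1.0) * ls
                - 0.5 * ssr / s2
                - 0.5 * s2 / pr.sd_prior_variance
            )

        acc1 = logu[:, i] < target(prop_ls) - target(cur_ls)
        log_sigma[:, i] = np.where(acc1, prop_ls, cur_ls)
        accepts["log_sigma"][:, i] += acc1

    # --- tau | theta, mu : random-walk MH on log scale --------------------
    if batch.three_level:
        ssr = ((state["theta"] - state["mu"][:, None]) ** 2).sum(axis=1)
        cur_lt = state["log_tau"]
        prop_lt = cur_lt + steps["log_tau"] * rng.standard_normal(B)

        def t_target(lt):
            t2 = np.exp(2.0 * lt)
            return (
                -(batch.n_types - 1.0) * lt
                - 0.5 * ssr / t2
                - 0.5 * t2 / pr.sd_prior_variance
            )

        acc2 = np.log(rng.random(B)) < t_target(prop_lt) - t_target(cur_lt)
        state["log_tau"] = np.where(acc2, prop_lt, cur_lt)
        accepts["log_tau"] += acc2


def _sample_batch(batch: _Batch, settings: McmcSettings, seed_seq) -> dict:
    """Run the sampler over the whole batch; returns raw draw arrays keyed
    by block name with shapes (B, K) or (B, K, dim)."""
    rng = np.random.default_rng(seed_seq)
    state = _initial_state(batch, rng)
    B, J = batch.B, batch.J
    steps = {
        "gamma": np.full((B, J), 0.3),
        "psi": np.full((B, J), 0.5),
        "log_sigma": np.full((B, batch.n_types), 0.5),
        "log_tau": np.full(B, 0.5),
    }
    accepts = {k: np.zeros_like(v) for k, v in steps.items()}

    K = settings.draws_per_chain
    out = {
        "gamma": np.empty((B, K, J)),
        "psi": np.empty((B, K, J)),
        "sigma": np.empty((B, K, batch.n_types)),
        "mu": np.empty((B, K)),
    }
    if batch.three_level:
        out["theta"] = np.empty((B, K, batch.n_types))
        out["tau"] = np.empty((B, K))
    if batch.has_alpha:
        out["alpha"] = np.empty((B, K))

    total = settings.burn_in + settings.n_keep
    kept = 0
    for it in range(total):
        _step(batch, state, steps, accepts, rng)
        in_burn = it < settings.burn_in
        if in_burn and (it + 1) % _ADAPT_WINDOW == 0:
            for k, acc in accepts.items():
                rate = acc / _ADAPT_WINDOW
                steps[k] = np.clip(
                    steps[k] * np.exp(1.5 * (rate - _TARGET_ACCEPT)), 1e-3, 10.0
                )
                acc[...] = 0.0
        if not in_burn and (it - settings.burn_in + 1) % settings.thin == 0:
            out["gamma"][:, kept] = state["gamma"]
            out["psi"][:, kept] = state["psi"]
            out["sigma"][:, kept] = np.exp(state["log_sigma"])
            out["mu"][:, kept] = state["mu"]
            if batch.three_level:
                out["theta"][:, kept] = state["theta"]
                out["tau"][:, kept] = np.exp(state["log_tau"])
            if batch.has_alpha:
                out["alpha"][:, kept] = state["alpha"]
            kept += 1
    return out


def _split_result(raw: dict, d: int, batch: _Batch, settings: McmcSettings, kind: str) -> PosteriorResult:
    """Extract dataset d from the batch into named scalar-parameter draws."""
    nc = batch.n_chains
    sl = slice(d * nc, (d + 1) * nc)
    draws = {}
    draws["mu"] = raw["mu"][sl]
    if batch.three_level:
        for i in range(batch.n_types):
            draws[f"theta[{i}]"] = raw["theta"][sl, :, i]
        draws["tau"] = raw["tau"][sl]
        for i in range(batch.n_types):
            draws[f"sigma[{i}]"] = raw["sigma"][sl, :, i]
    else:
        # two-level pooled effect doubles as the conventional theta
        draws["theta"] = raw["mu"][sl]
        draws["sigma"] = raw["sigma"][sl, :, 0]
    if batch.has_alpha:
        draws["alpha"] = raw["alpha"][sl]
    for j in range(batch.J):
        draws[f"gamma[{j}]"] = raw["gamma"][sl, :, j]
        draws[f"psi[{j}]"] = raw["psi"][sl, :, j]
    return PosteriorResult(draws=draws, settings=settings, kind=kind)


def fit(spec: ModelSpec, settings: Optional[McmcSettings] = None) -> PosteriorResult:
    """Fit one model specification by MCMC.

    Identical (spec, settings, seed) triples give identical draws.
    """
    settings = settings or McmcSettings()
    batch = _Batch([spec], settings.n_chains)
    raw = _sample_batch(batch, settings, np.random.SeedSequence(settings.seed))
    return _split_result(raw, 0, batch, settings, spec.kind)


def fit_many(
    specs: Sequence[ModelSpec], settings: Optional[McmcSettings] = None
) -> list[PosteriorResult]:
    """Fit many same-shaped specs (e.g. one per replicate dataset) in a
    single vectorised sampler pass.  Deterministic given the seed."""
    settings = settings or McmcSettings()
    batch = _Batch(list(specs), settings.n_chains)
    raw = _sample_batch(batch, settings, np.random.SeedSequence(settings.seed))
    return [
        _split_result(raw, d, batch, settings, specs[d].kind)
        for d in range(len(specs))
    ]
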