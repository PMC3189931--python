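"""Scikit-learn style estimator interface to the synthesis models.

Each estimator wraps one model specification and the MCMC engine:
``fit(X)`` takes a study table (a pandas DataFrame with the dataset
columns, or a Dataset) and exposes the posterior through fitted
attributes.  Parameters follow sklearn conventions (``get_params`` /
``set_params`` work, so the estimators compose with sklearn model
selection utilities).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .simulate import Dataset
from .models import (
    PriorSet,
    build_model,
    build_two_level,
    canonical_kind,
)
from .mcmc import McmcSettings, fit as mcmc_fit

__all__ = [
    "UnadjustedSynthesis",
    "DifferenceAdjustedSynthesis",
    "AggregateSynthesis",
    "InformativePriorSynthesis",
    "TwoLevelPooledSynthesis",
]


def _as_dataset(X: Union[Dataset, pd.DataFrame]) -> Dataset:
    if isinstance(X, Dataset):
        return X
    if isinstance(X, pd.DataFrame):
        return Dataset.from_frame(X)
    raise TypeError(
        "X must be a Dataset or a DataFrame with the study-table columns; "
        f"got {type(X).__name__}"
    )


class _BaseSynthesis(BaseEstimator):
    """Shared fit machinery; subclasses set ``_kind``."""

    _kind: str = ""

    def __init__(
        self,
        priors: Optional[PriorSet] = None,
        n_chains: int = 2,
        burn_in: int = 3000,
        n_keep: int = 5000,
        thin: int = 10,
        random_state: Optional[int] = None,
    ):
        self.priors = priors
        self.n_chains = n_chains
        self.burn_in = burn_in
        self.n_keep = n_keep
        self.thin = thin
        self.random_state = random_state

    def _settings(self) -> McmcSettings:
        return McmcSettings(
            n_chains=self.n_chains,
            burn_in=self.burn_in,
            n_keep=self.n_keep,
            thin=self.thin,
            seed=self.random_state,
        )

    def _build_spec(self, dataset: Dataset):
        return build_model(self._kind, dataset, self.priors)

    def fit(self, X, y=None):
        dataset = _as_dataset(X)
        self.spec_ = self._build_spec(dataset)
        self.result_ = mcmc_fit(self.spec_, self._settings())
        summ = self.result_.summaries
        self.summaries_ = summ
        self.mu_median_ = float(summ.loc["mu", "median"])
        self.mu_interval_ = (
            float(summ.loc["mu", "q2.5"]),
            float(summ.loc["mu", "q97.5"]),
        )
        self.psrf_mu_ = float(summ.loc["mu", "psrf"])
        if "alpha" in summ.index:
            self.alpha_median_ = float(summ.loc["alpha", "median"])
        self.n_features_in_ = dataset.to_frame().shape[1]
        return self

    def odds_ratio_(self):
        check_is_fitted(self, "mu_median_")
        return float(np.exp(self.mu_median_))


class UnadjustedSynthesis(_BaseSynthesis):
    """Three-level hierarchical synthesis, unadjusted for imbalances."""

    _kind = "unadjusted_I"


class DifferenceAdjustedSynthesis(_BaseSynthesis):
    """Three-level synthesis with a bias term proportional to the arm
    difference in the covariate (the imbalance-adjusted model)."""

    _kind = "difference_II"


class AggregateSynthesis(_BaseSynthesis):
    """Three-level synthesis with meta-regression on the study-level
    covariate aggregate (cannot see within-study imbalance)."""

    _kind = "aggregate_III"


class InformativePriorSynthesis(_BaseSynthesis):
    """Randomised-only likelihood with the non-randomised evidence entering
    as a variance-inflated informative prior on the pooled effect."""

    _kind = "informative_prior_IV"

    def __init__(
        self,
        priors: Optional[PriorSet] = None,
        inflation_factor: float = 4.0,
        n_chains: int = 2,
        burn_in: int = 3000,
        n_keep: int = 5000,
        thin: int = 10,
        random_state: Optional[int] = None,
    ):
        super().__init__(
            priors=priors,
            n_chains=n_chains,
            burn_in=burn_in,
            n_keep=n_keep,
            thin=thin,
            random_state=random_state,
        )
        self.inflation_factor = inflation_factor

    def _build_spec(self, dataset: Dataset):
        return build_model(
            self._kind,
            dataset,
            self.priors,
            inflation_factor=self.inflation_factor,
            mcmc_settings=self._settings(),
        )


class TwoLevelPooledSynthesis(_BaseSynthesis):
    """Simple Bayesian random-effects pooling of a single set of studies."""

    _kind = "two_level"

    def _build_spec(self, dataset: Dataset):
        return build_two_level(dataset.studies, self.priors)
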