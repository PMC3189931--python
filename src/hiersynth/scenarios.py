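"""Scenario configurations for the two-design simulation study.

A scenario fixes everything the data-generating model needs: how many
randomised (RCT) and non-randomised (NRS) studies to simulate, the per-arm
sample-size ranges, the true overall log odds ratio, the control-arm event
risk distribution, the age distributions per arm, and the strength of the
age imbalance (``alpha_age``, log odds ratio per year of arm age
difference).  Six built-in scenarios cross two imbalance strengths
(0.10, 0.50) with three study-portfolio shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ScenarioConfig",
    "beta_params_from_moments",
    "builtin_scenarios",
    "get_scenario",
    "load_scenario_yaml",
    "save_scenario_yaml",
]


def beta_params_from_moments(mean: float, variance: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the beta distribution with given moments.

    Uses the standard moment inversion ``a + b = m(1-m)/v - 1``.

    Raises
    ------
    ValueError
        If ``mean`` is outside (0, 1) or ``variance`` is outside
        ``(0, mean*(1-mean))`` — the open bound is required for positive
        shape parameters.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie strictly in (0, 1); got {mean}")
    bound = mean * (1.0 - mean)
    if not 0.0 < variance < bound:
        raise ValueError(
            f"beta variance must lie strictly in (0, mean*(1-mean)) = (0, {bound}); "
            f"got {variance}"
        )
    total = bound / variance - 1.0
    return mean * total, (1.0 - mean) * total


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid.

    Parameters follow the study design: equal arm sizes within a study,
    drawn uniformly from a range per study type; control-arm event
    probabilities beta-distributed; treatment/control mean ages uniform on
    per-arm ranges for non-randomised studies and identical across arms for
    randomised studies; the study-level log odds ratio is
    ``true_theta + alpha_age * (age_treatment - age_control)``.
    """

    scenario_id: int
    alpha_age: float
    n_randomised: int
    n_nonrandomised: int
    rct_arm_size_range: tuple[int, int]
    nrs_arm_size_range: tuple[int, int]
    true_theta: float = -0.20
    control_event_prob_mean: float = 0.04
    control_event_prob_var: float = 0.001
    age_treatment_range: tuple[float, float] = (75.0, 90.0)
    age_control_range: tuple[float, float] = (70.0, 85.0)

    def __post_init__(self):
        for name in ("rct_arm_size_range", "nrs_arm_size_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise ValueError(f"{name} must satisfy 1 <= low <= high; got ({lo}, {hi})")
        if self.n_randomised < 0 or self.n_nonrandomised < 0:
            raise ValueError("study counts must be non-negative")
        # raises if the beta moments are infeasible
        beta_params_from_moments(self.control_event_prob_mean, self.control_event_prob_var)

    @property
    def control_beta_shapes(self) -> tuple[float, float]:
        return beta_params_from_moments(
            self.control_event_prob_mean, self.control_event_prob_var
        )

    @property
    def n_studies(self) -> int:
        return self.n_randomised + self.n_nonrandomised

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rct_arm_size_range"] = list(self.rct_arm_size_range)
        d["nrs_arm_size_range"] = list(self.nrs_arm_size_range)
        d["age_treatment_range"] = list(self.age_treatment_range)
        d["age_control_range"] = list(self.age_control_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in (
            "rct_arm_size_range",
            "nrs_arm_size_range",
            "age_treatment_range",
            "age_control_range",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def builtin_scenarios() -> list[ScenarioConfig]:
    """The six built-in scenario configurations.

    Scenarios 1-3 use an imbalance impact of 0.10 log OR per year, 4-6 use
    0.50; within each triple the portfolio is (4 RCT + 4 NRS, both arm
    sizes 100-500), (4 RCT + 40 NRS), and (4 RCT + 4 NRS with NRS arms
    500-1000).  The true overall log odds ratio is -0.20 throughout.
    """
    grid = []
    for block, alpha in ((0, 0.10), (3, 0.50)):
        grid.append((block + 1, alpha, 4, 4, (100, 500), (100, 500)))
        grid.append((block + 2, alpha, 4, 40, (100, 500), (100, 500)))
        grid.append((block + 3, alpha, 4, 4, (100, 500), (500, 1000)))
    return [
        ScenarioConfig(
            scenario_id=sid,
            alpha_age=alpha,
            n_randomised=n_rct,
            n_nonrandomised=n_nrs,
            rct_arm_size_range=rct_range,
            nrs_arm_size_range=nrs_range,
        )
        for sid, alpha, n_rct, n_nrs, rct_range, nrs_range in grid
    ]


def get_scenario(ref: Union[int, str, Path, ScenarioConfig]) -> ScenarioConfig:
    """Resolve a scenario reference.

    Accepts an integer 1-6, a string ``"scenario:<k>"``, a YAML path, or a
    ScenarioConfig (returned unchanged).
    """
    if isinstance(ref, ScenarioConfig):
        return ref
    if isinstance(ref, str) and ref.startswith("scenario:"):
        ref = ref.split(":", 1)[1]
    try:
        sid = int(ref)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return load_scenario_yaml(Path(ref))  # type: ignore[arg-type]
    table = {c.scenario_id: c for c in builtin_scenarios()}
    if sid not in table:
        raise ValueError(
            f"unknown scenario id {sid}; built-in scenarios are {sorted(table)}"
        )
    return table[sid]


def load_scenario_yaml(path: Union[str, Path]) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def save_scenario_yaml(config: ScenarioConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
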