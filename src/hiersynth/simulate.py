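"""Data-generating model for two-arm binomial studies with age imbalance.

Each simulated study has equal-sized treatment and control arms.  The
control-arm event probability p_C is beta-distributed; the study log odds
ratio is psi = theta + alpha_age * (age_T - age_C); the treatment-arm
probability is expit(logit(p_C) + psi); event counts are binomial.
Randomised studies share a single age value across arms, so their psi is
exactly theta; only non-randomised studies carry imbalance-induced bias.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .scenarios import ScenarioConfig

__all__ = [
    "RANDOMISED",
    "NONRANDOMISED",
    "StudyRecord",
    "Dataset",
    "simulate_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]

RANDOMISED = "randomised"
NONRANDOMISED = "nonrandomised"

DATASET_COLUMNS = [
    "study_type",
    "study_index",
    "n_control",
    "r_control",
    "age_control",
    "n_treatment",
    "r_treatment",
    "age_treatment",
]
LATENT_COLUMNS = ["study_type", "study_index", "p_control", "p_treatment", "psi"]


@dataclass(frozen=True)
class StudyRecord:
    """One two-arm study: design type, arm sizes, event counts, arm mean ages."""

    study_type: str
    study_index: int
    n_control: int
    n_treatment: int
    r_control: int
    r_treatment: int
    age_control: float
    age_treatment: float

    def __post_init__(self):
        if self.study_type not in (RANDOMISED, NONRANDOMISED):
            raise ValueError(f"unknown study_type {self.study_type!r}")
        if not (0 <= self.r_control <= self.n_control):
            raise ValueError(
                f"study {self.study_index}: r_control={self.r_control} outside "
                f"[0, n_control={self.n_control}]"
            )
        if not (0 <= self.r_treatment <= self.n_treatment):
            raise ValueError(
                f"study {self.study_index}: r_treatment={self.r_treatment} outside "
                f"[0, n_treatment={self.n_treatment}]"
            )

    @property
    def age_difference(self) -> float:
        return self.age_treatment - self.age_control


@dataclass
class Dataset:
    """A simulated (or user-supplied) collection of studies.

    ``latent`` keeps the per-study true p_C, p_T and psi when the dataset
    was simulated, for validation; it is None for data read without a
    latent sidecar.
    """

    scenario: Optional[ScenarioConfig]
    studies: list[StudyRecord]
    latent: Optional[pd.DataFrame] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.scenario is not None:
            counts = {RANDOMISED: 0, NONRANDOMISED: 0}
            for s in self.studies:
                counts[s.study_type] += 1
            if counts[RANDOMISED] != self.scenario.n_randomised or counts[
                NONRANDOMISED
            ] != self.scenario.n_nonrandomised:
                raise ValueError(
                    "study counts do not match scenario: expected "
                    f"{self.scenario.n_randomised} randomised / "
                    f"{self.scenario.n_nonrandomised} non-randomised, got {counts}"
                )

    def __len__(self) -> int:
        return len(self.studies)

    def of_type(self, study_type: str) -> list[StudyRecord]:
        return [s for s in self.studies if s.study_type == study_type]

    @property
    def study_types(self) -> list[str]:
        return sorted({s.study_type for s in self.studies})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "study_type": s.study_type,
                    "study_index": s.study_index,
                    "n_control": s.n_control,
                    "r_control": s.r_control,
                    "age_control": s.age_control,
                    "n_treatment": s.n_treatment,
                    "r_treatment": s.r_treatment,
                    "age_treatment": s.age_treatment,
                }
                for s in self.studies
            ],
            columns=DATASET_COLUMNS,
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        scenario: Optional[ScenarioConfig] = None,
        latent: Optional[pd.DataFrame] = None,
    ) -> "Dataset":
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset table is missing columns: {missing}")
        studies = [
            StudyRecord(
                study_type=str(row.study_type),
                study_index=int(row.study_index),
                n_control=int(row.n_control),
                n_treatment=int(row.n_treatment),
                r_control=int(row.r_control),
                r_treatment=int(row.r_treatment),
                age_control=float(row.age_control),
                age_treatment=float(row.age_treatment),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(scenario=scenario, studies=studies, latent=latent)


def _simulate_type(
    rng: np.random.Generator,
    study_type: str,
    n_studies: int,
    arm_range: tuple[int, int],
    config: ScenarioConfig,
) -> tuple[list[StudyRecord], list[dict]]:
    a, b = config.control_beta_shapes
    lo, hi = arm_range
    records, latents = [], []
    for j in range(n_studies):
        # one substream per study keeps draws independent and reproducible
        n = int(rng.integers(lo, hi + 1))
        p_c = float(rng.beta(a, b))
        if study_type == RANDOMISED:
            age_c = age_t = float(rng.uniform(*config.age_control_range))
        else:
            age_t = float(rng.uniform(*config.age_treatment_range))
            age_c = float(rng.uniform(*config.age_control_range))
        psi = config.true_theta + config.alpha_age * (age_t - age_c)
        p_t = float(expit(logit(p_c) + psi))
        r_c = int(rng.binomial(n, p_c))
        r_t = int(rng.binomial(n, p_t))
        records.append(
            StudyRecord(
                study_type=study_type,
                study_index=j,
                n_control=n,
                n_treatment=n,
                r_control=r_c,
                r_treatment=r_t,
                age_control=age_c,
                age_treatment=age_t,
            )
        )
        latents.append(
            {
                "study_type": study_type,
                "study_index": j,
                "p_control": p_c,
                "p_treatment": p_t,
                "psi": psi,
            }
        )
    return records, latents


def simulate_dataset(config: ScenarioConfig, rng_seed: int) -> Dataset:
    """Draw one full dataset (all RCTs, then all NRS) under ``config``.

    The seed fully determines the dataset: a master ``SeedSequence`` is
    spawned into one child stream per study type, so adding studies of one
    type never perturbs the draws of the other.
    """
    ss = np.random.SeedSequence(rng_seed)
    child_rct, child_nrs = ss.spawn(2)
    records: list[StudyRecord] = []
    latents: list[dict] = []
    for study_type, n_studies, arm_range, child in (
        (RANDOMISED, config.n_randomised, config.rct_arm_size_range, child_rct),
        (NONRANDOMISED, config.n_nonrandomised, config.nrs_arm_size_range, child_nrs),
    ):
        recs, lats = _simulate_type(
            np.random.default_rng(child), study_type, n_studies, arm_range, config
        )
        records.extend(recs)
        latents.extend(lats)
    latent = pd.DataFrame(latents, columns=LATENT_COLUMNS)
    return Dataset(scenario=config, studies=records, latent=latent, seed=rng_seed)


def _write_csv_with_header(
    frame: pd.DataFrame, path: Union[str, Path], header_lines: Iterable[str]
) -> None:
    buf = io.StringIO()
    for line in header_lines:
        buf.write(f"# {line}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_dataset_csv(
    dataset: Dataset,
    path: Union[str, Path],
    latent_path: Optional[Union[str, Path]] = None,
    header_lines: Iterable[str] = (),
) -> None:
    """Write a dataset as CSV; the latent truth goes in a sidecar CSV."""
    _write_csv_with_header(dataset.to_frame(), path, header_lines)
    if latent_path is not None and dataset.latent is not None:
        _write_csv_with_header(dataset.latent, latent_path, header_lines)


def read_dataset_csv(
    path: Union[str, Path],
    latent_path: Optional[Union[str, Path]] = None,
    scenario: Optional[ScenarioConfig] = None,
) -> Dataset:
    frame = pd.read_csv(path, comment="#")
    latent = pd.read_csv(latent_path, comment="#") if latent_path else None
    return Dataset.from_frame(frame, scenario=scenario, latent=latent)
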