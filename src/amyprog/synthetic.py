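"""Seeded synthetic SUVR cohorts for fitting and testing.

Emulates the structure of a cross-sectional amyloid-PET study (a few
hundred elderly participants, one SUVR each): ages drawn uniformly
over a range, SUVR sampled from a generating 4-parameter logistic
plus Gaussian noise. Identical spec + seed gives identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import _logistic4

__all__ = ["SyntheticCohortSpec", "generate_suvr_cohort"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort dimensions and generating sigmoid.

    Defaults mirror the reference imaging study: 260 participants aged
    70-92, with a trajectory passing SUVR 1.5 at age 70.
    """

    n_subjects: int = 260
    age_min: float = 70.0
    age_max: float = 92.0
    # lower asymptote, upper asymptote, midpoint age, slope (1/year)
    sigmoid: tuple[float, float, float, float] = (1.0, 2.5, 75.8, 0.12)
    noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.age_min >= self.age_max:
            raise ValueError("age range must be non-degenerate")


def generate_suvr_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Table of (subject_id, age, suvr), reproducible under the seed."""
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(spec.age_min, spec.age_max, size=spec.n_subjects)
    truth = _logistic4(ages, *spec.sigmoid)
    suvr = truth + rng.normal(0.0, spec.noise_sd, size=spec.n_subjects)
    return pd.DataFrame({
        "subject_id": [f"S{k:04d}" for k in range(spec.n_subjects)],
        "age": ages,
        "suvr": suvr,
    })
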