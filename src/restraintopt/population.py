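"""Occupant covariate space: sampling, reference occupant, subgroups.

The occupant is described by three covariates — sex, stature (cm) and
body-mass index (kg/m^2).  The population of interest is bounded by per-sex
5th–95th percentile boxes; within those boxes occupants are weighted
uniformly (equal weight to every anthropometry, equal weight to each sex),
which is also the weighting used by the policy-optimization objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

Sex = Literal["male", "female"]

#: numeric encoding used wherever a covariate vector is required
SEX_CODE = {"male": 0.0, "female": 1.0}


@dataclass(frozen=True)
class OccupantCovariates:
    """One occupant: sex, stature in cm, BMI in kg/m^2."""

    sex: Sex
    stature_cm: float
    bmi: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (np.isfinite(self.stature_cm) and np.isfinite(self.bmi)):
            raise ValueError("stature and BMI must be finite")

    def as_numeric(self) -> np.ndarray:
        """Vector [sex_code, stature_cm, bmi] with male=0, female=1."""
        return np.array([SEX_CODE[self.sex], self.stature_cm, self.bmi])


@dataclass(frozen=True)
class CovariateBox:
    """Per-sex covariate ranges bounding the population.

    Defaults are stand-ins for the 5th–95th percentile adult ranges of a
    national anthropometric survey; they are configurable and carry no
    claim of matching any particular survey year.
    """

    male_stature: tuple[float, float] = (163.0, 186.0)
    male_bmi: tuple[float, float] = (20.5, 39.5)
    female_stature: tuple[float, float] = (150.0, 172.0)
    female_bmi: tuple[float, float] = (19.5, 42.5)

    def __post_init__(self) -> None:
        for name in ("male_stature", "male_bmi", "female_stature", "female_bmi"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: min must be < max, got ({lo}, {hi})")

    def stature_range(self, sex: Sex) -> tuple[float, float]:
        return self.male_stature if sex == "male" else self.female_stature

    def bmi_range(self, sex: Sex) -> tuple[float, float]:
        return self.male_bmi if sex == "male" else self.female_bmi

    def contains(self, s: OccupantCovariates) -> bool:
        st_lo, st_hi = self.stature_range(s.sex)
        b_lo, b_hi = self.bmi_range(s.sex)
        return st_lo <= s.stature_cm <= st_hi and b_lo <= s.bmi <= b_hi

    def union_stature(self) -> tuple[float, float]:
        """Stature range covering both sexes (used for standardization)."""
        return (min(self.male_stature[0], self.female_stature[0]),
                max(self.male_stature[1], self.female_stature[1]))

    def union_bmi(self) -> tuple[float, float]:
        return (min(self.male_bmi[0], self.female_bmi[0]),
                max(self.male_bmi[1], self.female_bmi[1]))


@dataclass(frozen=True)
class SubgroupRule:
    """Threshold rule defining a vulnerable subgroup.

    Directions are strict: 'above' means covariate > threshold, 'below'
    means covariate < threshold.
    """

    name: str
    sex: Sex
    bmi_threshold: float
    bmi_direction: Literal["above", "below"]
    stature_threshold: float
    stature_direction: Literal["above", "below"]

    def matches(self, s: OccupantCovariates) -> bool:
        if s.sex != self.sex:
            return False
        bmi_ok = (s.bmi > self.bmi_threshold if self.bmi_direction == "above"
                  else s.bmi < self.bmi_threshold)
        st_ok = (s.stature_cm > self.stature_threshold
                 if self.stature_direction == "above"
                 else s.stature_cm < self.stature_threshold)
        return bmi_ok and st_ok


def default_subgroup_rules() -> list[SubgroupRule]:
    """The two vulnerable subgroups analysed in the study.

    Tall obese males: BMI > 30.5 and stature > 181.7 cm (mean + 1 sd of the
    male covariates).  Short obese females: BMI > 37.3 and stature < 157 cm.
    """
    return [
        SubgroupRule("tall_obese_male", "male", 30.5, "above", 181.7, "above"),
        SubgroupRule("short_obese_female", "female", 37.3, "above", 157.0, "below"),
    ]


def subgroup_membership(
    s: OccupantCovariates, rules: Sequence[SubgroupRule]
) -> list[str]:
    """Labels of all rules matched by occupant ``s`` (possibly empty)."""
    return [r.name for r in rules if r.matches(s)]


def midsize_male_reference(
    config: OccupantCovariates | None = None,
) -> OccupantCovariates:
    """The 50th-percentile-male occupant used as the single-target baseline.

    Defaults to (male, 175.0 cm, BMI 25.6); pass an occupant to override.
    """
    if config is not None:
        return config
    return OccupantCovariates("male", 175.0, 25.6)


def sample_population(
    box: CovariateBox,
    n: int,
    seed: int,
    scheme: Literal["uniform", "space-filling"] = "uniform",
) -> list[OccupantCovariates]:
    """Draw ``n`` occupants with a 50/50 sex split (ties go to male).

    ``uniform`` draws stature and BMI independently and uniformly within
    the per-sex ranges; ``space-filling`` uses a seeded Latin hypercube per
    sex so the draw stratifies both continuous covariates.  Both schemes
    are bit-reproducible under an identical seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n_male = (n + 1) // 2
    counts = {"male": n_male, "female": n - n_male}
    rng = np.random.default_rng(seed)
    out: list[OccupantCovariates] = []
    for sex in ("male", "female"):
        k = counts[sex]
        if k == 0:
            continue
        st_lo, st_hi = box.stature_range(sex)
        b_lo, b_hi = box.bmi_range(sex)
        if scheme == "uniform":
            u = rng.uniform(size=(k, 2))
        elif scheme == "space-filling":
            sampler = qmc.LatinHypercube(d=2, seed=rng)
            u = sampler.random(k)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        stat = st_lo + (st_hi - st_lo) * u[:, 0]
        bmi = b_lo + (b_hi - b_lo) * u[:, 1]
        out.extend(
            OccupantCovariates(sex, float(stx), float(bx))
            for stx, bx in zip(stat, bmi)
        )
    return out


def population_to_frame(occupants: Iterable[OccupantCovariates]) -> pd.DataFrame:
    """Tabulate occupants with columns sex, stature_cm, bmi."""
    return pd.DataFrame(
        [(s.sex, s.stature_cm, s.bmi) for s in occupants],
        columns=["sex", "stature_cm", "bmi"],
    )


def population_from_frame(df: pd.DataFrame) -> list[OccupantCovariates]:
    return [
        OccupantCovariates(str(r.sex), float(r.stature_cm), float(r.bmi))
        for r in df.itertuples(index=False)
    ]


def population_numeric(occupants: Sequence[OccupantCovariates]) -> np.ndarray:
    """(n, 3) array of [sex_code, stature_cm, bmi] rows."""
    return np.array([s.as_numeric() for s in occupants])
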