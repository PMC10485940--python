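"""Input containers: mortality exposure/death schedules and unhealthy-prevalence schedules.

A :class:`MortalitySchedule` holds one sex x group block of period data: for each
single year of age, person-years of exposure and the death count observed over the
study window. Ages must be contiguous; cells may be *unobserved* (NaN in both
columns), which is how sparse subgroups with missing age cells are represented
before imputation.

A :class:`PrevalenceSchedule` holds the age pattern of the proportion unhealthy
pi_x under one of three definitions:

``DF``
    "disability-free": share reporting >= 2 weeks of illness from disease or
    accident (survey based).
``PH``
    "perceived health": share rating their own health poor or very poor.
``NHIS``
    claims based: share hospitalised for >= 7 days in the year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ScheduleValidationError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

HALE_DEFINITIONS = ("DF", "PH", "NHIS")

MORTALITY_COLUMNS = ["group_id", "sex", "age", "person_years", "deaths"]
PREVALENCE_COLUMNS = ["definition", "sex", "group_id", "age_lo", "age_hi", "pi", "denom"]


def compute_mx(deaths: np.ndarray, exposure: np.ndarray) -> np.ndarray:
    """Age-specific central death rate mx = deaths / person-years.

    Ages with zero or missing exposure are flagged missing (NaN), never divided.
    Negative counts are rejected.
    """
    deaths = np.asarray(deaths, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if deaths.shape != exposure.shape:
        raise ScheduleValidationError("deaths and exposure must be aligned")
    if np.any(deaths[np.isfinite(deaths)] < 0) or np.any(exposure[np.isfinite(exposure)] < 0):
        raise ScheduleValidationError("negative deaths or person-years")
    mx = np.full(deaths.shape, np.nan)
    ok = np.isfinite(deaths) & np.isfinite(exposure) & (exposure > 0)
    mx[ok] = deaths[ok] / exposure[ok]
    return mx


@dataclass(frozen=True)
class MortalitySchedule:
    """Observed deaths and person-years by single year of age for one sex x group."""

    group_id: str
    sex: str
    ages: np.ndarray
    exposure: np.ndarray
    deaths: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        exposure = np.asarray(self.exposure, dtype=float)
        deaths = np.asarray(self.deaths, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "exposure", exposure)
        object.__setattr__(self, "deaths", deaths)
        if self.sex not in SEXES:
            raise ScheduleValidationError(f"unknown sex label {self.sex!r}")
        if ages.ndim != 1 or len(ages) == 0:
            raise ScheduleValidationError("ages must be a non-empty 1-d array")
        if len({len(ages), len(exposure), len(deaths)}) != 1:
            raise ScheduleValidationError("ages, exposure and deaths must be aligned")
        if ages[0] < 0:
            raise ScheduleValidationError("first age must be >= 0")
        if np.any(np.diff(ages) != 1):
            raise ScheduleValidationError(
                "ages must be contiguous single years; encode missing cells as NaN"
            )
        # a cell is unobserved iff either column is NaN; normalise to both NaN
        missing = ~np.isfinite(exposure) | ~np.isfinite(deaths)
        exposure[missing] = np.nan
        deaths[missing] = np.nan
        if np.any(deaths[~missing] < 0) or np.any(exposure[~missing] < 0):
            raise ScheduleValidationError("negative deaths or person-years")
        bad = ~missing & (exposure == 0) & (deaths > 0)
        if np.any(bad):
            raise ScheduleValidationError(
                f"deaths recorded with zero exposure at ages {ages[bad].tolist()}"
            )

    @property
    def first_age(self) -> int:
        return int(self.ages[0])

    @property
    def oldest_age(self) -> int:
        return int(self.ages[-1])

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of ages with an observed (non-missing) cell."""
        return np.isfinite(self.exposure)

    @property
    def mx(self) -> np.ndarray:
        """Central death rates; NaN where unobserved or exposure is zero."""
        return compute_mx(self.deaths, self.exposure)

    @property
    def total_exposure(self) -> float:
        return float(np.nansum(self.exposure))

    @property
    def total_deaths(self) -> float:
        return float(np.nansum(self.deaths))

    def restrict(self, age_lo: int, age_hi: int) -> "MortalitySchedule":
        keep = (self.ages >= age_lo) & (self.ages <= age_hi)
        if not keep.any():
            raise ScheduleValidationError("restriction leaves no ages")
        return replace(
            self, ages=self.ages[keep], exposure=self.exposure[keep], deaths=self.deaths[keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": self.group_id,
                "sex": self.sex,
                "age": self.ages,
                "person_years": self.exposure,
                "deaths": self.deaths,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_id: str, sex: str) -> "MortalitySchedule":
        sub = frame[(frame["group_id"] == group_id) & (frame["sex"] == sex)]
        if sub.empty:
            raise ScheduleValidationError(f"no rows for group {group_id!r}, sex {sex!r}")
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy(dtype=int)
        # absent rows are another encoding of missing cells: reindex to contiguous
        full = np.arange(ages[0], ages[-1] + 1)
        exposure = np.full(full.shape, np.nan)
        deaths = np.full(full.shape, np.nan)
        idx = ages - ages[0]
        exposure[idx] = pd.to_numeric(sub["person_years"], errors="coerce").to_numpy()
        deaths[idx] = pd.to_numeric(sub["deaths"], errors="coerce").to_numpy()
        return cls(group_id=group_id, sex=sex, ages=full, exposure=exposure, deaths=deaths)


def read_mortality_csv(path) -> pd.DataFrame:
    """Read the mortality input CSV (columns group_id, sex, age, person_years, deaths)."""
    frame = pd.read_csv(path)
    missing = [c for c in MORTALITY_COLUMNS if c not in frame.columns]
    if missing:
        raise ScheduleValidationError(f"mortality CSV lacks columns {missing}")
    return frame


def schedules_from_frame(frame: pd.DataFrame) -> dict[tuple[str, str], MortalitySchedule]:
    out = {}
    for (gid, sex), _ in frame.groupby(["group_id", "sex"], sort=True):
        out[(gid, sex)] = MortalitySchedule.from_frame(frame, gid, sex)
    return out


@dataclass(frozen=True)
class PrevalenceSchedule:
    """Proportion unhealthy by age group under one HALE definition.

    ``age_lo``/``age_hi`` are inclusive group bounds; single-age schedules use
    age_lo == age_hi. ``denom`` (respondents or persons at risk) is optional and
    only needed when the prevalence-sampling variance term is requested.
    """

    definition: str
    age_lo: np.ndarray
    age_hi: np.ndarray
    pi: np.ndarray
    denom: np.ndarray | None = None
    group_id: str = ""
    sex: str = MALE

    def __post_init__(self):
        object.__setattr__(self, "age_lo", np.asarray(self.age_lo, dtype=int))
        object.__setattr__(self, "age_hi", np.asarray(self.age_hi, dtype=int))
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        if self.denom is not None:
            object.__setattr__(self, "denom", np.asarray(self.denom, dtype=float))
        if self.definition not in HALE_DEFINITIONS:
            raise ScheduleValidationError(
                f"definition must be one of {HALE_DEFINITIONS}, got {self.definition!r}"
            )
        if not (len(self.age_lo) == len(self.age_hi) == len(self.pi)):
            raise ScheduleValidationError("prevalence columns must be aligned")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ScheduleValidationError("pi must lie in [0, 1]")
        if np.any(self.age_hi < self.age_lo):
            raise ScheduleValidationError("age_hi must be >= age_lo")
        order = np.argsort(self.age_lo)
        if np.any(self.age_lo[order][1:] <= self.age_hi[order][:-1]):
            raise ScheduleValidationError("prevalence age groups overlap")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "definition": self.definition,
                "sex": self.sex,
                "group_id": self.group_id,
                "age_lo": self.age_lo,
                "age_hi": self.age_hi,
                "pi": self.pi,
                "denom": self.denom if self.denom is not None else np.nan,
            }
        )


def read_prevalence_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in PREVALENCE_COLUMNS if c not in frame.columns and c != "denom"]
    if missing:
        raise ScheduleValidationError(f"prevalence CSV lacks columns {missing}")
    if "denom" not in frame.columns:
        frame = frame.assign(denom=np.nan)
    return frame


def prevalence_from_frame(
    frame: pd.DataFrame, definition: str, group_id: str, sex: str
) -> PrevalenceSchedule:
    sub = frame[
        (frame["definition"] == definition)
        & (frame["group_id"] == group_id)
        & (frame["sex"] == sex)
    ].sort_values("age_lo")
    if sub.empty:
        raise ScheduleValidationError(
            f"no prevalence rows for ({definition}, {group_id}, {sex})"
        )
    denom = sub["denom"].to_numpy(dtype=float)
    return PrevalenceSchedule(
        definition=definition,
        age_lo=sub["age_lo"].to_numpy(dtype=int),
        age_hi=sub["age_hi"].to_numpy(dtype=int),
        pi=sub["pi"].to_numpy(dtype=float),
        denom=None if np.all(np.isnan(denom)) else denom,
        group_id=group_id,
        sex=sex,
    )
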