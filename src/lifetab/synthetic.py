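"""Synthetic registries with known ground truth.

The real inputs (a national disability registry linked to claims and survey
data) are restricted, so every pipeline stage is exercised against generated
data whose truth is analytic:

* adult mortality follows a Gompertz-Makeham hazard mu(x) = A + B c^x, with
  proportional subgroup hazard ratios;
* per-age person-years come from a stationary-population approximation
  (proportional to survival), scaled to a target total;
* deaths are Poisson given person-years (inputs are exposure-based);
* subgroups can start at a later first (registration) age and have a seeded
  random fraction of age cells blanked, emulating sparse disability types;
* unhealthy prevalence follows a four-parameter logistic in age per HALE
  definition, rising with age.

``analytic_le`` integrates the survival function numerically and is the oracle
recovery tests compare against. Everything is deterministic under the scenario
seed; scenarios serialise to YAML and round-trip.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .schedules import HALE_DEFINITIONS, MALE, MortalitySchedule, PrevalenceSchedule

#: integration grid step (years) for the analytic oracle
ORACLE_STEP = 0.01
#: integrate this far past max_age to close the tail
ORACLE_TAIL = 10


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic subpopulation."""

    group_id: str
    hazard_ratio: float = 1.0
    first_age: int = 0
    exposure_scale: float = 1e6  # target total person-years
    missing_age_fraction: float = 0.0

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not (0 <= self.missing_age_fraction < 1):
            raise ValueError("missing_age_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class PrevalenceCurve:
    """Logistic age pattern pi(x) = floor + (ceiling-floor) / (1 + exp(-slope (x - midpoint)))."""

    floor: float
    ceiling: float
    midpoint: float
    slope: float

    def __call__(self, ages) -> np.ndarray:
        x = np.asarray(ages, dtype=float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp(-self.slope * (x - self.midpoint))
        )


@dataclass(frozen=True)
class SyntheticScenario:
    """Full ground truth for one synthetic study."""

    makeham_A: float
    gompertz_B: float
    gompertz_c: float
    groups: tuple[GroupSpec, ...]
    prevalence_curves: dict
    max_age: int = 100
    sex: str = MALE
    seed: int = 20140101

    def __post_init__(self):
        if self.makeham_A < 0 or self.gompertz_B <= 0 or self.gompertz_c <= 1:
            raise ValueError("need A >= 0, B > 0, c > 1 for a valid senescent hazard")
        groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(**g) for g in self.groups
        )
        object.__setattr__(self, "groups", groups)
        curves = {}
        for defn, grp_curves in self.prevalence_curves.items():
            if defn not in HALE_DEFINITIONS:
                raise ValueError(f"unknown HALE definition {defn!r}")
            curves[defn] = {
                gid: c if isinstance(c, PrevalenceCurve) else PrevalenceCurve(**c)
                for gid, c in grp_curves.items()
            }
        object.__setattr__(self, "prevalence_curves", curves)

    def group(self, group_id: str) -> GroupSpec:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"no group {group_id!r} in scenario")

    def hazard(self, ages, hazard_ratio: float = 1.0) -> np.ndarray:
        """mu(x) = hr * (A + B c^x); proportional-hazards subgroups."""
        x = np.asarray(ages, dtype=float)
        return hazard_ratio * (self.makeham_A + self.gompertz_B * self.gompertz_c**x)

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path=None) -> str:
        payload = {
            "makeham_A": self.makeham_A,
            "gompertz_B": self.gompertz_B,
            "gompertz_c": self.gompertz_c,
            "max_age": self.max_age,
            "sex": self.sex,
            "seed": self.seed,
            "groups": [asdict(g) for g in self.groups],
            "prevalence_curves": {
                d: {gid: asdict(c) for gid, c in curves.items()}
                for d, curves in self.prevalence_curves.items()
            },
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SyntheticScenario":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source.read())
        else:
            text = str(source)
            if "\n" not in text and not text.strip().startswith("{"):
                with open(text, encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            else:
                payload = yaml.safe_load(text)
        return cls(**payload)


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------


def analytic_le(scenario: SyntheticScenario, group_id: str, age: float = None) -> float:
    """Remaining life expectancy at ``age`` by numeric integration of exp(-int mu).

    Integrates on a fine grid to max_age + 10 (the hazard there is large enough
    that the truncated tail is negligible at default parameters).
    """
    group = scenario.group(group_id)
    if age is None:
        age = group.first_age
    horizon = scenario.max_age + ORACLE_TAIL
    if age >= horizon:
        return 0.0
    grid = np.arange(age, horizon + ORACLE_STEP, ORACLE_STEP)
    mu = scenario.hazard(grid, group.hazard_ratio)
    cumhaz = np.concatenate([[0.0], np.cumsum((mu[1:] + mu[:-1]) / 2.0 * np.diff(grid))])
    surv = np.exp(-cumhaz)
    return float(np.trapezoid(surv, grid))


def stationary_exposure(
    scenario: SyntheticScenario, group: GroupSpec, ages: np.ndarray
) -> np.ndarray:
    """Person-years by age proportional to mid-interval survival from first_age."""
    grid = np.arange(group.first_age, ages[-1] + 1 + ORACLE_STEP, ORACLE_STEP)
    mu = scenario.hazard(grid, group.hazard_ratio)
    cumhaz = np.concatenate([[0.0], np.cumsum((mu[1:] + mu[:-1]) / 2.0 * np.diff(grid))])
    surv = np.exp(-cumhaz)
    mid_idx = np.round((ages + 0.5 - group.first_age) / ORACLE_STEP).astype(int)
    mid_idx = np.clip(mid_idx, 0, len(surv) - 1)
    shape = surv[mid_idx]
    return group.exposure_scale * shape / shape.sum()


def mask_ages(
    schedule: MortalitySchedule, fraction: float, rng: np.random.Generator
) -> MortalitySchedule:
    """Blank a random subset of age cells (never the first age) to NaN."""
    if fraction <= 0:
        return schedule
    candidates = np.arange(1, len(schedule.ages))
    k = int(round(fraction * len(candidates)))
    drop = rng.choice(candidates, size=k, replace=False)
    exposure = schedule.exposure.copy()
    deaths = schedule.deaths.copy()
    exposure[drop] = np.nan
    deaths[drop] = np.nan
    return replace(schedule, exposure=exposure, deaths=deaths)


def simulate_schedule(
    scenario: SyntheticScenario,
    group_id: str,
    rng: np.random.Generator | None = None,
) -> MortalitySchedule:
    """Draw one exposure/deaths schedule for a group.

    Exposure is the deterministic stationary shape; deaths are Poisson with
    mean exposure * mu(x + 1/2) * hazard_ratio. A seeded subset of ages is then
    blanked per the group's ``missing_age_fraction``.
    """
    group = scenario.group(group_id)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed, _group_index(scenario, group_id)])
        )
    ages = np.arange(group.first_age, scenario.max_age + 1)
    exposure = stationary_exposure(scenario, group, ages)
    mu_mid = scenario.hazard(ages + 0.5, group.hazard_ratio)
    deaths = rng.poisson(exposure * mu_mid).astype(float)
    sched = MortalitySchedule(
        group_id=group_id, sex=scenario.sex, ages=ages, exposure=exposure, deaths=deaths
    )
    return mask_ages(sched, group.missing_age_fraction, rng)


def _group_index(scenario: SyntheticScenario, group_id: str) -> int:
    return [g.group_id for g in scenario.groups].index(group_id)


def simulate_prevalence(
    scenario: SyntheticScenario,
    group_id: str,
    definition: str,
    ages: np.ndarray | None = None,
    denom: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PrevalenceSchedule:
    """Evaluate (or binomially sample, when ``denom`` given) the prevalence curve."""
    group = scenario.group(group_id)
    curve = scenario.prevalence_curves[definition][group_id]
    if ages is None:
        ages = np.arange(group.first_age, scenario.max_age + 1)
    ages = np.asarray(ages, dtype=int)
    pi = np.clip(curve(ages), 0.0, 1.0)
    if denom is not None:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [scenario.seed, 7919, _group_index(scenario, group_id)]
                )
            )
        denom = np.asarray(denom, dtype=float)
        pi = rng.binomial(denom.astype(int), pi) / np.maximum(denom, 1.0)
    return PrevalenceSchedule(
        definition=definition, age_lo=ages, age_hi=ages, pi=pi,
        denom=denom, group_id=group_id, sex=scenario.sex,
    )


# ---------------------------------------------------------------------------
# stock scenarios
# ---------------------------------------------------------------------------

# Gompertz-Makeham parameters calibrated (once, by numeric search on the
# analytic oracle) so the male reference e0 is ~81.3 y; the disabled-group
# hazard ratio then puts its e0 in the high 60s, as in the registry magnitudes
# the generator emulates.
_MALE_A = 3.0e-4
_MALE_B = 1.1372e-5
_MALE_C = 1.1093


def default_scenario(seed: int = 20140101) -> SyntheticScenario:
    """Reference study conditions: a large reference population, a pooled
    disabled group with elevated mortality, and sparse subgroup "types" with
    later first ages and missing cells, mirroring registry magnitudes."""
    groups = (
        GroupSpec("reference", hazard_ratio=1.0, first_age=0, exposure_scale=1.2e8),
        GroupSpec("disabled", hazard_ratio=3.2, first_age=0, exposure_scale=7.3e6),
        GroupSpec("type_sensory", hazard_ratio=1.4, first_age=0,
                  exposure_scale=7.5e5, missing_age_fraction=0.1),
        GroupSpec("type_mental", hazard_ratio=2.0, first_age=12,
                  exposure_scale=2.5e5, missing_age_fraction=0.3),
        GroupSpec("type_organ", hazard_ratio=3.5, first_age=1,
                  exposure_scale=4.5e4, missing_age_fraction=0.45),
    )
    base_curves = {
        "DF": PrevalenceCurve(floor=0.08, ceiling=0.60, midpoint=74.0, slope=0.08),
        "PH": PrevalenceCurve(floor=0.06, ceiling=0.65, midpoint=78.0, slope=0.09),
        "NHIS": PrevalenceCurve(floor=0.02, ceiling=0.45, midpoint=85.0, slope=0.09),
    }
    dis_curves = {
        "DF": PrevalenceCurve(floor=0.18, ceiling=0.70, midpoint=70.0, slope=0.08),
        "PH": PrevalenceCurve(floor=0.15, ceiling=0.72, midpoint=74.0, slope=0.09),
        "NHIS": PrevalenceCurve(floor=0.08, ceiling=0.50, midpoint=80.0, slope=0.09),
    }
    curves = {
        d: {
            "reference": base_curves[d],
            "disabled": dis_curves[d],
            "type_sensory": dis_curves[d],
            "type_mental": dis_curves[d],
            "type_organ": dis_curves[d],
        }
        for d in HALE_DEFINITIONS
    }
    return SyntheticScenario(
        makeham_A=_MALE_A, gompertz_B=_MALE_B, gompertz_c=_MALE_C,
        groups=groups, prevalence_curves=curves, max_age=100, seed=seed,
    )


def crossover_scenario(seed: int = 20140101) -> SyntheticScenario:
    """Old-age prevalence crossover: the reference group's unhealthy share
    rises steeply after 70 while the disabled group's plateaus, so the HALE
    difference (reference - disabled) changes sign at old ages."""
    groups = (
        GroupSpec("reference", hazard_ratio=1.0, first_age=0, exposure_scale=1.2e8),
        GroupSpec("disabled", hazard_ratio=3.2, first_age=0, exposure_scale=7.3e6),
    )
    curves = {
        "NHIS": {
            "reference": PrevalenceCurve(floor=0.02, ceiling=0.97, midpoint=80.0, slope=0.28),
            "disabled": PrevalenceCurve(floor=0.16, ceiling=0.34, midpoint=60.0, slope=0.10),
        }
    }
    return SyntheticScenario(
        makeham_A=_MALE_A, gompertz_B=_MALE_B, gompertz_c=_MALE_C,
        groups=groups, prevalence_curves=curves, max_age=100, seed=seed,
    )
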