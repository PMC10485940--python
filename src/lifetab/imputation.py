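"""Sparse-subgroup rate imputation and abridged (5-year) tables.

Small disability types lack deaths at many ages. Their missing age-specific
rates are borrowed from the all-group *standard* table through a logit-scale
linear link fitted on the ages both series observe:

    logit(mx_type) = a + b * logit(mx_standard)

The link is monotone (for b > 0) and maps predictions back into (0, 1).
Observed cells are never altered; only gaps are filled. Complete tables are
then collapsed to 5-year age groups for reporting, with the expectation at a
group start taken directly from the complete table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .errors import ScheduleValidationError
from .lifetable import LifeTable, RateSchedule, Z95
from .schedules import MortalitySchedule

logger = logging.getLogger(__name__)

DEFAULT_GROUP_STARTS = tuple([0] + list(range(5, 90, 5)))  # 0, 5, ..., 85+


@dataclass(frozen=True)
class RateLink:
    """Fitted logit-scale linear link between a standard and an observed rate series."""

    intercept: float
    slope: float
    fit_ages: np.ndarray
    residual_sd: float
    fallback: bool = False  # constant-ratio fallback used (too few ages)

    def predict(self, standard_mx: np.ndarray) -> np.ndarray:
        # central rates can exceed 1 (e.g. at the closure age); the logit link
        # lives on (0, 1), so clamp before transforming
        std = np.clip(np.asarray(standard_mx, dtype=float), 1e-12, 1.0 - 1e-12)
        eta = self.intercept + self.slope * logit(std)
        return expit(eta)


def fit_rate_link(
    standard_mx: np.ndarray,
    observed_mx: np.ndarray,
    ages_observed: np.ndarray,
    weights: np.ndarray | None = None,
) -> RateLink:
    """Least-squares fit of logit(observed) on logit(standard) over observed ages.

    Rates must lie in (0, 1); ages where either series is 0, 1 or missing are
    dropped. With fewer than 3 usable ages the link degenerates to a constant
    logit-scale offset (slope 1), i.e. a pooled ratio in the small-rate regime.
    ``weights`` (e.g. exposure) turn the fit into weighted least squares.
    """
    standard_mx = np.asarray(standard_mx, dtype=float)
    observed_mx = np.asarray(observed_mx, dtype=float)
    ages_observed = np.asarray(ages_observed, dtype=int)
    ok = (
        np.isfinite(standard_mx) & np.isfinite(observed_mx)
        & (standard_mx > 0) & (standard_mx < 1)
        & (observed_mx > 0) & (observed_mx < 1)
    )
    xs = logit(standard_mx[ok])
    ys = logit(observed_mx[ok])
    if ok.sum() < 3:
        logger.warning(
            "only %d usable ages; falling back to constant-offset link", int(ok.sum())
        )
        offset = float(np.mean(ys - xs)) if ok.sum() else 0.0
        sd = float(np.std(ys - xs - offset, ddof=0)) if ok.sum() > 1 else 0.0
        return RateLink(offset, 1.0, ages_observed[ok], sd, fallback=True)
    X = sm.add_constant(xs)
    if weights is not None:
        res = sm.WLS(ys, X, weights=np.asarray(weights, dtype=float)[ok]).fit()
    else:
        res = sm.OLS(ys, X).fit()
    a, b = res.params
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ScheduleValidationError("rate link coefficients are not finite")
    return RateLink(
        intercept=float(a), slope=float(b), fit_ages=ages_observed[ok],
        residual_sd=float(np.sqrt(res.scale)),
    )


def impute_missing_mx(
    schedule: MortalitySchedule,
    standard_mx: np.ndarray,
    standard_ages: np.ndarray,
    link: RateLink,
) -> RateSchedule:
    """Fill missing age cells with the link-transformed standard rates.

    The standard series must cover every target age. Observed cells pass
    through untouched; the result is contiguous and ready for table building.
    """
    standard_ages = np.asarray(standard_ages, dtype=int)
    idx = np.searchsorted(standard_ages, schedule.ages)
    if (
        np.any(idx >= len(standard_ages))
        or np.any(standard_ages[np.minimum(idx, len(standard_ages) - 1)] != schedule.ages)
    ):
        raise ScheduleValidationError("standard table does not cover all target ages")
    std = np.asarray(standard_mx, dtype=float)[idx]
    mx = schedule.mx.copy()
    missing = ~np.isfinite(mx)
    mx[missing] = link.predict(std[missing])
    return RateSchedule(
        group_id=schedule.group_id, sex=schedule.sex, ages=schedule.ages,
        mx=mx, deaths=schedule.deaths,
    )


def impute_from_standard(
    schedule: MortalitySchedule, standard: LifeTable | RateSchedule
) -> tuple[RateSchedule, RateLink]:
    """Convenience: fit the link on the observed ages, then impute the gaps."""
    std_ages = standard.ages
    std_mx = standard.mx
    idx = np.searchsorted(std_ages, schedule.ages)
    if np.any(idx >= len(std_ages)) or np.any(std_ages[np.minimum(idx, len(std_ages) - 1)] != schedule.ages):
        raise ScheduleValidationError("standard table does not cover all target ages")
    link = fit_rate_link(np.asarray(std_mx)[idx], schedule.mx, schedule.ages)
    return impute_missing_mx(schedule, std_mx, std_ages, link), link


# ---------------------------------------------------------------------------
# abridged tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbridgedLifeTable:
    """5-year reporting view of a complete table (open group at the last start)."""

    group_id: str
    sex: str
    frame: pd.DataFrame  # age_group, start, nmx, nqx, lx, nLx, Tx, ex, se_ex

    def ex_at(self, start: int) -> float:
        row = self.frame[self.frame["start"] == start]
        if row.empty:
            raise KeyError(f"no age group starting at {start}")
        return float(row["ex"].iloc[0])


def abridge(
    complete: LifeTable,
    group_starts=DEFAULT_GROUP_STARTS,
    group_id: str = "",
    sex: str = "male",
) -> AbridgedLifeTable:
    """Collapse a complete table to grouped rows.

    ``ex`` (and its se) at a group start are the complete-table values at that
    exact age, so abridging is purely a reporting operation. Group starts below
    the table's first age are clamped to it (types registered later in life
    start their first group there).
    """
    starts = sorted(set(int(s) for s in group_starts))
    starts = [s for s in starts if s <= complete.closure_age]
    clamped = [max(s, complete.first_age) for s in starts]
    clamped = sorted(set(clamped))
    if not clamped:
        raise ScheduleValidationError("no group starts within the table range")
    rows = []
    bounds = clamped + [complete.closure_age + 1]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (complete.ages >= lo) & (complete.ages < hi)
        i = int(np.searchsorted(complete.ages, lo))
        nLx = float(np.sum(complete.Lx[sel]))
        ndx = float(np.sum(complete.dx[sel]))
        is_open = hi > complete.closure_age
        label = f"{lo}+" if is_open else f"{lo}-{hi - 1}"
        rows.append(
            {
                "age_group": label,
                "start": lo,
                "nmx": ndx / nLx if nLx > 0 else np.nan,
                "nqx": 1.0 if is_open else (
                    ndx / complete.lx[i] if complete.lx[i] > 0 else np.nan
                ),
                "lx": float(complete.lx[i]),
                "nLx": nLx,
                "Tx": float(complete.Tx[i]),
                "ex": float(complete.ex[i]),
                "se_ex": float(complete.se_ex[i]) if complete.se_ex is not None else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    frame["lo95"] = frame["ex"] - Z95 * frame["se_ex"]
    frame["hi95"] = frame["ex"] + Z95 * frame["se_ex"]
    return AbridgedLifeTable(group_id=group_id, sex=sex, frame=frame)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class RateLinkModel:
    """Model object for the standard-to-type rate link."""

    def __init__(
        self,
        schedule: MortalitySchedule,
        standard: LifeTable | RateSchedule,
        weights: np.ndarray | None = None,
    ):
        self.schedule = schedule
        self.standard = standard
        self.weights = weights

    def fit(self) -> "RateLinkResults":
        imputed, link = impute_from_standard(self.schedule, self.standard)
        return RateLinkResults(self, link, imputed)


class RateLinkResults:
    def __init__(self, model: RateLinkModel, link: RateLink, imputed: RateSchedule):
        self.model = model
        self.link = link
        self.imputed = imputed

    @property
    def params(self) -> dict:
        return {"intercept": self.link.intercept, "slope": self.link.slope}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_id": self.model.schedule.group_id,
                    "sex": self.model.schedule.sex,
                    "intercept": self.link.intercept,
                    "slope": self.link.slope,
                    "residual_sd": self.link.residual_sd,
                    "n_fit_ages": len(self.link.fit_ages),
                    "fallback": self.link.fallback,
                }
            ]
        )
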