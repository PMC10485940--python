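"""Sullivan-method healthy life expectancy (HALE) with Chiang-type intervals.

The Sullivan estimator down-weights each age's person-years lived by the
proportion healthy:

    HALE_x = sum_{i >= x} L_i (1 - pi_i) / l_x

where pi_i is the proportion unhealthy at age i under one of the three
definitions (DF: two-week illness; PH: poor self-rated health; NHIS: >= 7
hospital days in claims). Survey prevalence arrives in age groups and is
expanded to single ages by a step function (a monotone spline is available
behind a flag).

The default 95% interval treats prevalence as fixed and propagates only the
mortality sampling variation, i.e. Chiang's estimator with the remaining-LE
term replaced by remaining HALE and the within-interval term scaled by the
healthy fraction. An additional binomial prevalence-variance term can be
switched on when survey denominators are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PrevalenceCoverageError, ScheduleValidationError
from .lifetable import LifeTable, Z95
from .schedules import PrevalenceSchedule

logger = logging.getLogger(__name__)


def expand_prevalence(
    grouped: PrevalenceSchedule,
    target_ages: np.ndarray,
    method: str = "step",
) -> np.ndarray:
    """Expand grouped prevalence to one value per single age.

    ``step`` (default): each age inherits its group's pi. ``spline``: monotone
    piecewise-cubic (PCHIP) through the group midpoints, clipped to [0, 1].
    Ages below the youngest group inherit its value (logged); ages above the
    oldest group, or falling in an interior gap, raise an error naming the gap.
    """
    target_ages = np.asarray(target_ages, dtype=int)
    order = np.argsort(grouped.age_lo)
    lo = grouped.age_lo[order]
    hi = grouped.age_hi[order]
    pi = grouped.pi[order]

    below = target_ages < lo[0]
    if below.any():
        logger.info(
            "ages %d-%d below the first prevalence group; carrying pi=%.4f downward",
            target_ages[below][0], target_ages[below][-1], pi[0],
        )
    above = target_ages > hi[-1]
    if above.any():
        raise PrevalenceCoverageError(
            f"prevalence schedule ends at age {hi[-1]} but ages up to "
            f"{target_ages[-1]} are required"
        )
    idx = np.searchsorted(hi, target_ages)
    idx = np.clip(idx, 0, len(lo) - 1)
    in_gap = (target_ages > hi[np.maximum(idx - 1, 0)]) & (target_ages < lo[idx])
    if in_gap.any():
        a = target_ages[in_gap][0]
        raise PrevalenceCoverageError(f"no prevalence group covers age {a}")
    if method == "step":
        return pi[idx]
    if method == "spline":
        from scipy.interpolate import PchipInterpolator

        mids = (lo + hi) / 2.0
        if len(mids) < 2:
            return pi[idx]
        spline = PchipInterpolator(mids, pi, extrapolate=False)
        out = spline(np.clip(target_ages, mids[0], mids[-1]))
        return np.clip(out, 0.0, 1.0)
    raise ValueError(f"unknown expansion method {method!r}")


@dataclass(frozen=True)
class HALETable:
    """Healthy life expectancy by age under one prevalence definition."""

    definition: str
    ages: np.ndarray
    hale: np.ndarray
    pi: np.ndarray
    se_hale: np.ndarray | None = None

    @property
    def lo95(self) -> np.ndarray:
        return self.hale - Z95 * self.se_hale

    @property
    def hi95(self) -> np.ndarray:
        return self.hale + Z95 * self.se_hale

    def hale_at(self, age: int) -> float:
        return float(self.hale[np.searchsorted(self.ages, age)])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"age": self.ages, "pi": self.pi, "hale": self.hale}
        )
        if self.se_hale is not None:
            frame["se_hale"] = self.se_hale
            frame["lo95"] = self.lo95
            frame["hi95"] = self.hi95
        return frame


def sullivan(
    lifetable: LifeTable, pi: np.ndarray, definition: str = "NHIS"
) -> HALETable:
    """Sullivan HALE at every age, open interval included with its own pi."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != lifetable.ages.shape:
        raise ScheduleValidationError("prevalence must cover the life-table ages")
    if np.any(pi < 0) or np.any(pi > 1):
        raise ScheduleValidationError("pi must lie in [0, 1]")
    healthy_L = lifetable.Lx * (1.0 - pi)
    tail = np.cumsum(healthy_L[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        hale = np.where(lifetable.lx > 0, tail / lifetable.lx, 0.0)
    return HALETable(definition=definition, ages=lifetable.ages, hale=hale, pi=pi)


def sullivan_variance(
    lifetable: LifeTable,
    pi: np.ndarray,
    deaths: np.ndarray,
    prevalence_variance: bool = False,
    denom: np.ndarray | None = None,
    square_bracket: bool = True,
) -> np.ndarray:
    """Chiang-type sampling variance of HALE.

    Mortality part: Chiang's recursion with e_{j+1} replaced by HALE_{j+1} and
    the within-interval term (1 - a_j) scaled by the healthy fraction
    (1 - pi_j). Optional prevalence part (``prevalence_variance=True``):
    binomial term sum (Lbar_j/l_x)^2 pi_j (1 - pi_j) / denom_j, requiring
    per-age denominators.
    """
    deaths = np.asarray(deaths, dtype=float)
    pi = np.asarray(pi, dtype=float)
    table = lifetable
    q = table.qx
    n = len(q)
    s2p = np.zeros(n)
    ok = (q > 0) & (q < 1) & np.isfinite(deaths) & (deaths > 0)
    missing = (q > 0) & (q < 1) & ~ok
    if np.any(missing):
        logger.warning(
            "no death counts at ages %s; HALE variance contribution set to 0",
            table.ages[missing].tolist(),
        )
    s2p[ok] = q[ok] ** 2 * (1.0 - q[ok]) / deaths[ok]

    hale = sullivan(table, pi).hale
    h_next = np.append(hale[1:], 0.0)
    bracket = (1.0 - table.ax) * (1.0 - pi) + h_next
    if square_bracket:
        bracket = bracket**2
    contrib = table.lx**2 * bracket * s2p
    tail = np.cumsum(contrib[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(table.lx > 0, tail / table.lx**2, 0.0)

    if prevalence_variance:
        if denom is None:
            raise ScheduleValidationError(
                "prevalence-variance term requires per-age denominators"
            )
        denom = np.asarray(denom, dtype=float)
        var_pi = np.where(denom > 0, pi * (1.0 - pi) / denom, 0.0)
        prev_contrib = table.Lx**2 * var_pi
        prev_tail = np.cumsum(prev_contrib[::-1])[::-1]
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = s2 + np.where(table.lx > 0, prev_tail / table.lx**2, 0.0)
    return s2


def sullivan_ci(
    lifetable: LifeTable,
    pi: np.ndarray,
    deaths: np.ndarray,
    definition: str = "NHIS",
    prevalence_variance: bool = False,
    denom: np.ndarray | None = None,
) -> HALETable:
    """HALE with 95% intervals hale +/- 1.96 se."""
    base = sullivan(lifetable, pi, definition)
    s2 = sullivan_variance(
        lifetable, pi, deaths, prevalence_variance=prevalence_variance, denom=denom
    )
    return HALETable(
        definition=definition, ages=base.ages, hale=base.hale, pi=base.pi,
        se_hale=np.sqrt(s2),
    )


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class SullivanModel:
    """Sullivan HALE estimator over a fitted life table.

    Accepts a :class:`lifetab.lifetable.LifeTableResults` (preferred; carries
    death counts for the interval) or a bare :class:`LifeTable` plus deaths.
    """

    def __init__(
        self,
        lifetable_results,
        prevalence: PrevalenceSchedule,
        deaths: np.ndarray | None = None,
        expansion: str = "step",
        prevalence_variance: bool = False,
    ):
        from .lifetable import LifeTableResults

        if isinstance(lifetable_results, LifeTableResults):
            self.table = lifetable_results.table
            self.deaths = lifetable_results.deaths
        else:
            self.table = lifetable_results
            self.deaths = deaths if deaths is not None else np.full(
                len(self.table.ages), np.nan
            )
        self.prevalence = prevalence
        self.expansion = expansion
        self.prevalence_variance = prevalence_variance

    def fit(self) -> "SullivanResults":
        pi = expand_prevalence(self.prevalence, self.table.ages, self.expansion)
        denom = None
        if self.prevalence_variance:
            if self.prevalence.denom is None:
                raise ScheduleValidationError(
                    "prevalence-variance term requires denominators in the schedule"
                )
            denom = expand_prevalence(
                PrevalenceSchedule(
                    definition=self.prevalence.definition,
                    age_lo=self.prevalence.age_lo,
                    age_hi=self.prevalence.age_hi,
                    pi=np.clip(self.prevalence.denom / self.prevalence.denom.max(), 0, 1),
                ),
                self.table.ages,
                "step",
            ) * self.prevalence.denom.max()
        hale = sullivan_ci(
            self.table, pi, self.deaths, definition=self.prevalence.definition,
            prevalence_variance=self.prevalence_variance, denom=denom,
        )
        return SullivanResults(self, hale)


class SullivanResults:
    def __init__(self, model: SullivanModel, hale_table: HALETable):
        self.model = model
        self.hale_table = hale_table

    @property
    def hale(self) -> np.ndarray:
        return self.hale_table.hale

    @property
    def definition(self) -> str:
        return self.hale_table.definition

    def unhealthy_le(self) -> np.ndarray:
        """Unhealthy life expectancy = ex - HALE at every age."""
        return self.model.table.ex - self.hale_table.hale

    def summary(self, report_ages=None) -> pd.DataFrame:
        frame = self.hale_table.to_frame()
        if report_ages is not None:
            frame = frame[frame["age"].isin(report_ages)]
        return frame.reset_index(drop=True)
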