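"""Complete period life tables with Greville graduation and Chiang confidence intervals.

The construction follows the classical single-decrement recipe used by national
statistical offices:

1. central death rates ``mx = deaths / person-years``;
2. death probabilities ``qx = mx / (1 + (1 - ax) mx)`` with Coale-Demeny infant
   separation factors (a0 = 0.05 for males, 0.13 for females) and ax = 0.5 above
   age 0;
3. graduation of qx by a symmetric local least-squares cubic ("Greville"
   graduation, default 9-point window);
4. the lx / dx / Lx / Tx / ex recursion with an open-ended closure interval,
   exponential closure ``L_w = l_w / m_w``;
5. Chiang's estimator of the sampling variance of ex,

   ``S2_ex = lx^-2 * sum_j lj^2 [(1 - a_j) + e_{j+1}]^2 * S2_pj``,
   ``S2_pj = qj^2 (1 - qj) / Dj``,

   giving 95% intervals ``ex +/- 1.96 se``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import ScheduleValidationError
from .schedules import FEMALE, MALE, MortalitySchedule, compute_mx

logger = logging.getLogger(__name__)

#: Coale-Demeny separation factor at age 0 by sex.
INFANT_AX = {MALE: 0.05, FEMALE: 0.13}

DEFAULT_RADIX = 100_000.0
Z95 = 1.96


@dataclass(frozen=True)
class RateSchedule:
    """A contiguous set of central death rates, with death counts where observed.

    This is the hand-off object between rate-producing stages (old-age extension,
    imputation) and table construction: extrapolated or imputed ages carry a rate
    but no observed exposure, so ``deaths`` is NaN there and those ages contribute
    nothing to the Chiang variance.
    """

    group_id: str
    sex: str
    ages: np.ndarray
    mx: np.ndarray
    deaths: np.ndarray | None = None

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        mx = np.asarray(self.mx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "mx", mx)
        if self.deaths is not None:
            object.__setattr__(self, "deaths", np.asarray(self.deaths, dtype=float))
        if np.any(np.diff(ages) != 1):
            raise ScheduleValidationError("rate schedule ages must be contiguous")
        if np.any(mx[np.isfinite(mx)] < 0):
            raise ScheduleValidationError("negative rates")

    @classmethod
    def from_mortality(cls, schedule: MortalitySchedule) -> "RateSchedule":
        return cls(
            group_id=schedule.group_id,
            sex=schedule.sex,
            ages=schedule.ages,
            mx=schedule.mx,
            deaths=schedule.deaths,
        )

    @property
    def first_age(self) -> int:
        return int(self.ages[0])


def assign_ax(sex: str, ages: np.ndarray, infant_ax: dict | None = None) -> np.ndarray:
    """Per-age separation factors: sex-specific Coale-Demeny value at age 0, 0.5 above."""
    if sex not in INFANT_AX:
        raise ScheduleValidationError(f"unknown sex label {sex!r}")
    ages = np.asarray(ages, dtype=int)
    table = dict(INFANT_AX)
    if infant_ax:
        table.update(infant_ax)
    ax = np.full(ages.shape, 0.5)
    ax[ages == 0] = table[sex]
    return ax


def mx_to_qx(mx: np.ndarray, ax: np.ndarray | float) -> np.ndarray:
    """Death probability qx = mx / (1 + (1 - ax) mx), capped at 1.

    NaN rates propagate (missing stays missing).
    """
    mx = np.asarray(mx, dtype=float)
    ax = np.broadcast_to(np.asarray(ax, dtype=float), mx.shape)
    if np.any(mx[np.isfinite(mx)] < 0):
        raise ScheduleValidationError("mx must be >= 0")
    if np.any((ax < 0) | (ax > 1)):
        raise ScheduleValidationError("ax must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        qx = mx / (1.0 + (1.0 - ax) * mx)
    return np.minimum(qx, 1.0)


def qx_to_mx(qx: np.ndarray, ax: np.ndarray | float) -> np.ndarray:
    """Inverse of :func:`mx_to_qx`; infinite at qx = 1/(1-ax) and beyond."""
    qx = np.asarray(qx, dtype=float)
    ax = np.broadcast_to(np.asarray(ax, dtype=float), qx.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - (1.0 - ax) * qx
        mx = np.where(denom > 0, qx / denom, np.inf)
    return mx


def greville_smooth(
    qx: np.ndarray, order: int = 9, weights: np.ndarray | None = None
) -> np.ndarray:
    """Graduate a qx series by a symmetric moving local-cubic fit of width ``order``.

    The graduation reproduces polynomials of degree <= 3 exactly (the defining
    property of Greville-type formulas); endpoints are handled by evaluating the
    boundary-window polynomial, i.e. a one-sided fit. Output is clipped to [0, 1].

    Custom symmetric convolution ``weights`` (length ``order``) may be supplied to
    drop in published graduation coefficients; interior points then use the
    convolution and endpoint ages are left unsmoothed.

    Series shorter than the window are passed through unchanged with a warning.
    """
    qx = np.asarray(qx, dtype=float)
    if order < 5 or order % 2 == 0:
        raise ValueError("order must be an odd integer >= 5")
    if len(qx) < order:
        logger.warning("series of length %d shorter than window %d; graduation skipped",
                       len(qx), order)
        warnings.warn("series shorter than graduation window; passed through", stacklevel=2)
        return qx.copy()
    if np.any(~np.isfinite(qx)):
        raise ScheduleValidationError("graduation requires a gap-free qx series")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != order:
            raise ValueError("weights must have length equal to order")
        half = order // 2
        smoothed = qx.copy()
        smoothed[half:-half] = np.convolve(qx, weights[::-1], mode="valid")
    else:
        smoothed = savgol_filter(qx, window_length=order, polyorder=3, mode="interp")
    return np.clip(smoothed, 0.0, 1.0)


@dataclass(frozen=True)
class LifeTable:
    """A complete life table; the open-ended closure interval is the last row."""

    ages: np.ndarray
    mx: np.ndarray
    ax: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    radix: float
    closure_mx: float
    se_ex: np.ndarray | None = None

    @property
    def closure_age(self) -> int:
        return int(self.ages[-1])

    @property
    def first_age(self) -> int:
        return int(self.ages[0])

    def ex_at(self, age: int) -> float:
        return float(self.ex[np.searchsorted(self.ages, age)])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "age": self.ages,
                "mx": self.mx,
                "ax": self.ax,
                "qx": self.qx,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )
        if self.se_ex is not None:
            frame["se_ex"] = self.se_ex
            frame["lo95"] = self.ex - Z95 * self.se_ex
            frame["hi95"] = self.ex + Z95 * self.se_ex
        return frame


def build_life_table(
    ages: np.ndarray,
    qx: np.ndarray,
    ax: np.ndarray,
    radix: float = DEFAULT_RADIX,
    closure_mx: float | None = None,
    mx: np.ndarray | None = None,
) -> LifeTable:
    """Run the lx/dx/Lx/Tx/ex recursion over a gap-free qx series.

    The last supplied age starts the open-ended interval: its q is forced to 1
    and its person-years are ``l / closure_mx`` (exponential closure). When no
    closure rate is available the triangular fallback ``L = ax * l`` is used.
    """
    ages = np.asarray(ages, dtype=int)
    qx = np.asarray(qx, dtype=float).copy()
    ax = np.broadcast_to(np.asarray(ax, dtype=float), qx.shape).copy()
    if radix <= 0:
        raise ValueError("radix must be positive")
    if np.any(~np.isfinite(qx)) or np.any(qx < 0) or np.any(qx > 1):
        raise ScheduleValidationError("qx must be finite and in [0, 1]")
    n = len(qx)
    qx[-1] = 1.0  # open-ended interval

    lx = np.empty(n)
    dx = np.empty(n)
    lx[0] = radix
    for i in range(n - 1):
        dx[i] = lx[i] * qx[i]
        lx[i + 1] = lx[i] - dx[i]
    dx[-1] = lx[-1]

    Lx = np.empty(n)
    lx_next = np.append(lx[1:], 0.0)
    Lx[:-1] = lx_next[:-1] + ax[:-1] * dx[:-1]
    if closure_mx is not None and closure_mx > 0 and np.isfinite(closure_mx):
        Lx[-1] = lx[-1] / closure_mx
    else:
        logger.info("no closure rate supplied; using triangular closure L = ax * l")
        Lx[-1] = ax[-1] * lx[-1]

    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)

    if mx is None:
        mx = qx_to_mx(qx, ax)
        if closure_mx is not None:
            mx = mx.copy()
            mx[-1] = closure_mx
    return LifeTable(
        ages=ages, mx=np.asarray(mx, dtype=float), ax=ax, qx=qx, lx=lx, dx=dx,
        Lx=Lx, Tx=Tx, ex=ex, radix=radix,
        closure_mx=float(closure_mx) if closure_mx else np.nan,
    )


def chiang_variance(
    table: LifeTable,
    deaths: np.ndarray,
    square_bracket: bool = True,
) -> np.ndarray:
    """Chiang's sampling variance of ex at every age.

    ``deaths`` are observed death counts aligned to the table's ages; NaN or zero
    counts at ages with q in (0, 1) contribute zero variance (with a warning), as
    do extrapolated ages without observations.

    ``square_bracket=False`` reproduces the literal unsquared bracket sometimes
    seen in print, for sensitivity checks only.
    """
    deaths = np.asarray(deaths, dtype=float)
    if deaths.shape != table.ages.shape:
        raise ScheduleValidationError("deaths must align with table ages")
    q = table.qx
    n = len(q)
    s2p = np.zeros(n)
    interior = (q > 0) & (q < 1)
    no_count = interior & (~np.isfinite(deaths) | (deaths <= 0))
    if np.any(no_count):
        logger.warning(
            "no death counts at ages %s with q in (0,1); variance contribution set to 0",
            table.ages[no_count].tolist(),
        )
    ok = interior & np.isfinite(deaths) & (deaths > 0)
    s2p[ok] = q[ok] ** 2 * (1.0 - q[ok]) / deaths[ok]

    e_next = np.append(table.ex[1:], 0.0)
    bracket = (1.0 - table.ax) + e_next
    if square_bracket:
        bracket = bracket**2
    contrib = table.lx**2 * bracket * s2p
    tail = np.cumsum(contrib[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        s2e = np.where(table.lx > 0, tail / table.lx**2, 0.0)
    return s2e


@dataclass(frozen=True)
class ChiangInterval:
    """95% confidence interval for remaining life expectancy at one age."""

    age: int
    ex_point: float
    se_ex: float
    lo95: float
    hi95: float


def chiang_ci(
    table: LifeTable, deaths: np.ndarray, square_bracket: bool = True
) -> list[ChiangInterval]:
    """Per-age Chiang 95% intervals ex +/- 1.96 se."""
    s2e = chiang_variance(table, deaths, square_bracket=square_bracket)
    se = np.sqrt(s2e)
    return [
        ChiangInterval(
            age=int(a), ex_point=float(e), se_ex=float(s),
            lo95=float(e - Z95 * s), hi95=float(e + Z95 * s),
        )
        for a, e, s in zip(table.ages, table.ex, se)
    ]


def with_se(table: LifeTable, deaths: np.ndarray, square_bracket: bool = True) -> LifeTable:
    """Return a copy of the table carrying se_ex from Chiang's estimator."""
    se = np.sqrt(chiang_variance(table, deaths, square_bracket=square_bracket))
    return replace(table, se_ex=se)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class LifeTableModel:
    """Smoothed complete life table estimator for one mortality schedule.

    Parameters
    ----------
    schedule
        Observed exposure/deaths (``MortalitySchedule``) or pre-computed rates
        (``RateSchedule``, e.g. after extension or imputation). Must be gap-free;
        impute sparse schedules first.
    smooth_order
        Window of the Greville-type graduation of qx; ``None`` disables smoothing.
    extension
        Optional :class:`lifetab.extension.ExtensionConfig`; when given, old-age
        rates are replaced by the selected parametric family before the table is
        built.
    radix
        Starting cohort size l0.
    """

    def __init__(
        self,
        schedule: MortalitySchedule | RateSchedule,
        smooth_order: int | None = 9,
        extension=None,
        radix: float = DEFAULT_RADIX,
        infant_ax: dict | None = None,
    ):
        if isinstance(schedule, MortalitySchedule):
            self.source = schedule
            self.rates = RateSchedule.from_mortality(schedule)
        else:
            self.source = None
            self.rates = schedule
        self.smooth_order = smooth_order
        self.extension = extension
        self.radix = radix
        self.infant_ax = infant_ax

    def fit(self) -> "LifeTableResults":
        rates = self.rates
        extension_fit = None
        if self.extension is not None:
            from .extension import extend_rates  # local import avoids a cycle

            if self.source is None:
                raise ScheduleValidationError(
                    "old-age extension requires an observed MortalitySchedule"
                )
            rates, extension_fit = extend_rates(self.source, self.extension)

        mx = rates.mx
        if np.any(~np.isfinite(mx)):
            raise ScheduleValidationError(
                f"rate schedule for {rates.group_id!r} has missing ages; impute first"
            )
        ax = assign_ax(rates.sex, rates.ages, self.infant_ax)
        qx = mx_to_qx(mx, ax)
        if self.smooth_order:
            if extension_fit is not None:
                # graduate only the observed span; model rates are already smooth
                cut = np.searchsorted(rates.ages, extension_fit.splice_age)
                qx = qx.copy()
                qx[:cut] = greville_smooth(qx[:cut], self.smooth_order)
            else:
                qx = greville_smooth(qx, self.smooth_order)
        table = build_life_table(
            rates.ages, qx, ax, radix=self.radix, closure_mx=float(mx[-1]), mx=mx
        )
        deaths = rates.deaths if rates.deaths is not None else np.full(len(mx), np.nan)
        table = with_se(table, deaths)
        return LifeTableResults(self, table, deaths, extension_fit)


class LifeTableResults:
    """Fitted life table: point estimates, Chiang uncertainty, diagnostics."""

    def __init__(self, model: LifeTableModel, table: LifeTable, deaths, extension_fit=None):
        self.model = model
        self.table = table
        self.deaths = deaths
        self.extension_fit = extension_fit
        self.group_id = model.rates.group_id
        self.sex = model.rates.sex

    @property
    def ex(self) -> np.ndarray:
        return self.table.ex

    @property
    def se_ex(self) -> np.ndarray:
        return self.table.se_ex

    @property
    def e0(self) -> float:
        return float(self.table.ex[0])

    def confint(self) -> pd.DataFrame:
        se = self.table.se_ex
        return pd.DataFrame(
            {"age": self.table.ages, "lo95": self.table.ex - Z95 * se,
             "hi95": self.table.ex + Z95 * se}
        )

    def to_frame(self) -> pd.DataFrame:
        return self.table.to_frame()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self, report_ages=None) -> pd.DataFrame:
        """Compact report (2-decimal display is left to the caller/reporting layer)."""
        frame = self.to_frame()
        if report_ages is not None:
            frame = frame[frame["age"].isin(report_ages)]
        cols = ["age", "mx", "qx", "lx", "ex", "se_ex", "lo95", "hi95"]
        out = frame[[c for c in cols if c in frame.columns]].reset_index(drop=True)
        out.attrs["group_id"] = self.group_id
        out.attrs["sex"] = self.sex
        return out

    def __repr__(self):
        e = self.table
        return (
            f"<LifeTableResults {self.group_id}/{self.sex}: ages "
            f"{e.first_age}-{e.closure_age}, e{e.first_age}="
            f"{e.ex[0]:.2f}>"
        )
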