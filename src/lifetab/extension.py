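"""Old-age mortality extension: fit parametric hazard families, pick the best,
extrapolate rates beyond the reliable-data range, and splice them back in.

Registry of nine candidate families (all fitted by least squares on log mx over
a common window, so criterion values are directly comparable):

==================  ==========================================================
``gompertz``        mx = B c^x
``makeham``         mx = A + B c^x
``kannisto``        mx = u/(1+u), u = B c^x  (2-parameter logistic)
``heligman_pollard``old-age term G H^x on the odds of death; in rate form
                    mx = u/(1+u/2), u = G H^x (midpoint separation factor)
``perks``           mx = B c^x / (1 + D c^x)  (logistic with free asymptote)
``weibull``         mx = a x^b
``coale_kisker``    log mx quadratic in age with the rate pinned to a closure
                    value at age 110 (constant deceleration of the rate of
                    mortality increase)
``denuit_goderniaux`` log mx = c (x - 130)^2  (quadratic closing at age 130)
``log_quadratic``   log mx = a + b x + c x^2 (unconstrained)
==================  ==========================================================

Ties in the criterion (within 1e-12) are broken by the fixed priority order
above, which places each constrained family ahead of the families that nest it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar, nnls

from .errors import ExtensionFitError, ScheduleValidationError
from .lifetable import RateSchedule
from .schedules import MortalitySchedule

logger = logging.getLogger(__name__)

TIE_TOL = 1e-12

#: fixed documented priority order; earlier wins criterion ties
FAMILY_PRIORITY = (
    "gompertz",
    "makeham",
    "kannisto",
    "heligman_pollard",
    "perks",
    "weibull",
    "coale_kisker",
    "denuit_goderniaux",
    "log_quadratic",
)

# Coale-Kisker closure: pin the central rate at this age to this value.
CK_PIN_AGE = 110
CK_PIN_RATE = 1.0
DG_CLOSE_AGE = 130


# ---------------------------------------------------------------------------
# per-family fit/predict (least squares on log mx)
# ---------------------------------------------------------------------------


def _fit_gompertz(x, logm):
    b, a = np.polyfit(x, logm, 1)
    return {"B": float(np.exp(a)), "c": float(np.exp(b))}


def _predict_gompertz(x, p):
    return p["B"] * p["c"] ** np.asarray(x, dtype=float)


def _fit_makeham(x, logm):
    m = np.exp(logm)

    def profile(logc):
        # for fixed c the model is linear in (A, B); non-negative least squares
        design = np.vstack([np.ones_like(x), np.exp(logc * x)]).T
        (A, B), _ = nnls(design, m)
        pred = np.maximum(A + B * np.exp(logc * x), 1e-300)
        return float(np.sum((np.log(pred) - logm) ** 2)), (A, B)

    grid = np.linspace(0.005, 0.25, 50)
    losses = [profile(g)[0] for g in grid]
    g0 = grid[int(np.argmin(losses))]
    ref = minimize_scalar(
        lambda g: profile(g)[0],
        bounds=(max(g0 - 0.01, 1e-4), g0 + 0.01), method="bounded",
        options={"xatol": 1e-12},
    )
    logc = float(ref.x)
    loss0, (A, B) = profile(logc)

    def resid(theta):
        A_, logB, logc_ = theta
        return np.log(np.maximum(A_ + np.exp(logB + logc_ * x), 1e-300)) - logm

    if B > 0:  # polish; keep whichever solution has the lower criterion
        sol = least_squares(
            resid,
            x0=[A, float(np.clip(np.log(B), -199.0, 9.0)), logc],
            bounds=([0.0, -200.0, 1e-6], [np.inf, 10.0, 1.0]),
            max_nfev=2000,
        )
        if np.all(np.isfinite(sol.x)) and 2 * sol.cost < loss0:
            A, B, logc = sol.x[0], float(np.exp(sol.x[1])), sol.x[2]
    if not np.all(np.isfinite([A, B, logc])):
        raise ExtensionFitError("makeham fit did not converge")
    return {"A": float(A), "B": float(B), "c": float(np.exp(logc))}


def _predict_makeham(x, p):
    return p["A"] + p["B"] * p["c"] ** np.asarray(x, dtype=float)


def _logistic_linear_fit(x, u):
    """Fit log u = log B + x log c by least squares."""
    b, a = np.polyfit(x, np.log(u), 1)
    return float(np.exp(a)), float(np.exp(b))


def _fit_kannisto(x, logm):
    m = np.exp(logm)
    if np.any(m >= 1):
        raise ExtensionFitError("kannisto requires rates < 1 on the window")
    B, c = _logistic_linear_fit(x, m / (1.0 - m))
    return {"B": B, "c": c}


def _predict_kannisto(x, p):
    u = p["B"] * p["c"] ** np.asarray(x, dtype=float)
    return u / (1.0 + u)


def _fit_heligman_pollard(x, logm):
    m = np.exp(logm)
    if np.any(m >= 2):
        raise ExtensionFitError("heligman-pollard rate form requires mx < 2")
    B, c = _logistic_linear_fit(x, m / (1.0 - 0.5 * m))
    return {"G": B, "H": c}


def _predict_heligman_pollard(x, p):
    u = p["G"] * p["H"] ** np.asarray(x, dtype=float)
    return u / (1.0 + 0.5 * u)


def _fit_perks(x, logm):
    m = np.exp(logm)

    def loss_for_logc(logc):
        # for fixed c, 1/m = (1/B) c^-x + D/B is linear
        z = np.exp(-logc * x)
        A = np.vstack([z, np.ones_like(z)]).T
        coef, *_ = np.linalg.lstsq(A, 1.0 / m, rcond=None)
        alpha, beta = coef
        if alpha <= 0:
            return np.inf, None
        B = 1.0 / alpha
        D = max(beta * B, 0.0)
        pred = np.log(B) + logc * x - np.log1p(D * np.exp(logc * x))
        return float(np.sum((pred - logm) ** 2)), (B, D)

    grid = np.linspace(0.01, 0.25, 49)
    losses = [loss_for_logc(g)[0] for g in grid]
    g0 = grid[int(np.argmin(losses))]
    ref = minimize_scalar(
        lambda g: loss_for_logc(g)[0], bracket=None,
        bounds=(max(g0 - 0.02, 1e-4), g0 + 0.02), method="bounded",
        options={"xatol": 1e-10},
    )
    logc = float(ref.x)
    _, bd = loss_for_logc(logc)
    if bd is None:
        raise ExtensionFitError("perks profile fit failed")
    B, D = bd

    def resid(theta):
        logB, logc_, sD = theta
        u = np.exp(logB + logc_ * x)
        return np.log(u / (1.0 + sD**2 * np.exp(logc_ * x))) - logm

    sol = least_squares(
        resid, x0=[np.log(B), logc, np.sqrt(max(D, 1e-12))], max_nfev=2000,
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise ExtensionFitError("perks refinement did not converge")
    logB, logc_, sD = sol.x
    return {"B": float(np.exp(logB)), "c": float(np.exp(logc_)), "D": float(sD**2)}


def _predict_perks(x, p):
    cx = p["c"] ** np.asarray(x, dtype=float)
    return p["B"] * cx / (1.0 + p["D"] * cx)


def _fit_weibull(x, logm):
    if np.any(np.asarray(x) <= 0):
        raise ExtensionFitError("weibull requires positive ages")
    b, a = np.polyfit(np.log(x), logm, 1)
    return {"a": float(np.exp(a)), "b": float(b)}


def _predict_weibull(x, p):
    return p["a"] * np.asarray(x, dtype=float) ** p["b"]


def _fit_log_quadratic(x, logm):
    c2, c1, c0 = np.polyfit(x, logm, 2)
    return {"a": float(c0), "b": float(c1), "c": float(c2)}


def _predict_log_quadratic(x, p):
    x = np.asarray(x, dtype=float)
    return np.exp(p["a"] + p["b"] * x + p["c"] * x**2)


def _fit_coale_kisker(x, logm, pin_rate=CK_PIN_RATE):
    # log m = t0 + t1 x + t2 x^2 subject to value log(pin_rate) at CK_PIN_AGE
    y = logm - np.log(pin_rate)
    A = np.vstack([x - CK_PIN_AGE, x**2 - CK_PIN_AGE**2]).T
    (t1, t2), *_ = np.linalg.lstsq(A, y, rcond=None)
    t0 = np.log(pin_rate) - CK_PIN_AGE * t1 - CK_PIN_AGE**2 * t2
    return {"a": float(t0), "b": float(t1), "c": float(t2), "pin_rate": float(pin_rate)}


def _predict_coale_kisker(x, p):
    x = np.asarray(x, dtype=float)
    return np.exp(p["a"] + p["b"] * x + p["c"] * x**2)


def _fit_denuit_goderniaux(x, logm):
    v = (np.asarray(x, dtype=float) - DG_CLOSE_AGE) ** 2
    c = float(np.sum(v * logm) / np.sum(v**2))
    return {"c": c}


def _predict_denuit_goderniaux(x, p):
    return np.exp(p["c"] * (np.asarray(x, dtype=float) - DG_CLOSE_AGE) ** 2)


@dataclass(frozen=True)
class FamilySpec:
    name: str
    n_params: int
    fit: callable
    predict: callable


FAMILIES: dict[str, FamilySpec] = {
    "gompertz": FamilySpec("gompertz", 2, _fit_gompertz, _predict_gompertz),
    "makeham": FamilySpec("makeham", 3, _fit_makeham, _predict_makeham),
    "kannisto": FamilySpec("kannisto", 2, _fit_kannisto, _predict_kannisto),
    "heligman_pollard": FamilySpec(
        "heligman_pollard", 2, _fit_heligman_pollard, _predict_heligman_pollard
    ),
    "perks": FamilySpec("perks", 3, _fit_perks, _predict_perks),
    "weibull": FamilySpec("weibull", 2, _fit_weibull, _predict_weibull),
    "coale_kisker": FamilySpec("coale_kisker", 2, _fit_coale_kisker, _predict_coale_kisker),
    "denuit_goderniaux": FamilySpec(
        "denuit_goderniaux", 1, _fit_denuit_goderniaux, _predict_denuit_goderniaux
    ),
    "log_quadratic": FamilySpec("log_quadratic", 3, _fit_log_quadratic, _predict_log_quadratic),
}


# ---------------------------------------------------------------------------
# fitting, selection, splicing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtensionFit:
    """A fitted old-age family and its extrapolated rates."""

    family: str
    params: dict
    fit_window: tuple[int, int]
    criterion_value: float
    extended_ages: np.ndarray
    extended_mx: np.ndarray
    splice_age: int | None = None

    def predict(self, ages) -> np.ndarray:
        return FAMILIES[self.family].predict(np.asarray(ages, dtype=float), self.params)


@dataclass(frozen=True)
class ExtensionConfig:
    """Configuration of the extension stage (config keys ``extension.*``)."""

    families: tuple[str, ...] = FAMILY_PRIORITY
    fit_window: tuple[int, int] = (65, 84)
    splice_age: int | None = None  # default: fit_window upper bound + 1
    blend_width: int = 5
    max_age: int = 100
    criterion: str = "sse_log_mx"
    family_override: str | None = None  # force one family (e.g. coale_kisker)

    def resolved_splice(self) -> int:
        return self.splice_age if self.splice_age is not None else self.fit_window[1] + 1


def _window_data(schedule: MortalitySchedule, fit_window):
    lo, hi = fit_window
    mask = (schedule.ages >= lo) & (schedule.ages <= hi) & schedule.observed
    mx = schedule.mx
    with np.errstate(invalid="ignore"):
        pos = mask & (mx > 0)
    dropped = mask & ~pos
    if np.any(dropped):
        logger.warning(
            "zero/invalid rates at ages %s excluded from the fit window",
            schedule.ages[dropped].tolist(),
        )
    return schedule.ages[pos].astype(float), mx[pos]


def fit_extension_model(
    schedule: MortalitySchedule,
    family: str,
    fit_window: tuple[int, int] = (65, 84),
    max_age: int = 100,
) -> ExtensionFit:
    """Least-squares fit of one family on log mx over the window; deterministic."""
    if family not in FAMILIES:
        raise ExtensionFitError(f"unknown family {family!r}")
    spec = FAMILIES[family]
    x, m = _window_data(schedule, fit_window)
    if len(x) < spec.n_params + 2:
        raise ExtensionFitError(
            f"window {fit_window} has {len(x)} usable ages; "
            f"{family} needs at least {spec.n_params + 2}"
        )
    logm = np.log(m)
    params = spec.fit(x, logm)
    fitted = spec.predict(x, params)
    if np.any(~np.isfinite(fitted)) or np.any(fitted <= 0):
        raise ExtensionFitError(f"{family} produced non-finite/non-positive fitted rates")
    criterion = float(np.sum((np.log(fitted) - logm) ** 2))
    ext_ages = np.arange(fit_window[1] + 1, max_age + 1)
    ext_mx = spec.predict(ext_ages.astype(float), params)
    if np.any(~np.isfinite(ext_mx)) or np.any(ext_mx <= 0):
        raise ExtensionFitError(f"{family} extrapolation is not strictly positive")
    return ExtensionFit(
        family=family, params=params, fit_window=tuple(fit_window),
        criterion_value=criterion, extended_ages=ext_ages, extended_mx=ext_mx,
    )


def select_extension_model(
    schedule: MortalitySchedule,
    families=FAMILY_PRIORITY,
    fit_window: tuple[int, int] = (65, 84),
    max_age: int = 100,
    return_table: bool = False,
):
    """Fit every candidate and return the converged fit with minimal criterion.

    Ties within ``TIE_TOL`` are broken by :data:`FAMILY_PRIORITY` regardless of
    the order families were supplied in. The per-family selection table is
    logged (and returned when ``return_table``).
    """
    fits: dict[str, ExtensionFit] = {}
    failures: dict[str, str] = {}
    for family in families:
        try:
            fits[family] = fit_extension_model(schedule, family, fit_window, max_age)
        except (ExtensionFitError, np.linalg.LinAlgError) as exc:
            failures[family] = str(exc)
            logger.warning("family %s failed on %s: %s", family, schedule.group_id, exc)
    if not fits:
        raise ExtensionFitError(
            f"all families failed on window {fit_window} for group {schedule.group_id!r}"
        )
    table = pd.DataFrame(
        [
            {
                "family": name,
                "criterion": fits[name].criterion_value if name in fits else np.nan,
                "status": "ok" if name in fits else f"failed: {failures[name]}",
                "params": fits[name].params if name in fits else None,
            }
            for name in families
        ]
    )
    logger.info("extension selection for %s:\n%s", schedule.group_id, table.to_string())
    best_value = min(f.criterion_value for f in fits.values())
    tied = [n for n, f in fits.items() if f.criterion_value <= best_value + TIE_TOL]
    winner = min(tied, key=FAMILY_PRIORITY.index)
    if return_table:
        return fits[winner], table
    return fits[winner]


def extend_and_blend(
    schedule: MortalitySchedule,
    fit: ExtensionFit,
    splice_age: int,
    max_age: int = 100,
    blend_width: int = 5,
) -> RateSchedule:
    """Splice model rates onto the observed schedule from ``splice_age`` upward.

    Rates below the splice are untouched. To avoid a jump at the splice, the
    log-rate offset between the last observed rate and the model is tapered
    linearly to zero over ``blend_width`` years (width 0 = hard splice).
    Observed death counts are retained where kept; extrapolated ages carry NaN.
    """
    if splice_age < schedule.first_age or splice_age > schedule.oldest_age + 1:
        raise ScheduleValidationError("splice_age must lie within or just beyond the data")
    if max_age < splice_age:
        raise ScheduleValidationError("max_age must be >= splice_age")
    ages = np.arange(schedule.first_age, max_age + 1)
    mx = np.full(ages.shape, np.nan)
    deaths = np.full(ages.shape, np.nan)
    n_keep = splice_age - schedule.first_age
    obs_mx = schedule.mx
    mx[:n_keep] = obs_mx[:n_keep]
    deaths[:n_keep] = schedule.deaths[:n_keep]
    # observed counts at replaced-but-observed ages still inform the variance
    n_obs = min(len(schedule.ages), len(ages))
    deaths[n_keep:n_obs] = schedule.deaths[n_keep:n_obs]

    model_ages = ages[n_keep:]
    log_model = np.log(fit.predict(model_ages.astype(float)))
    if blend_width > 0 and n_keep > 0 and np.isfinite(obs_mx[n_keep - 1]) and obs_mx[n_keep - 1] > 0:
        delta = np.log(obs_mx[n_keep - 1]) - np.log(
            float(fit.predict(np.array([splice_age - 1.0]))[0])
        )
        steps = np.arange(1, len(model_ages) + 1)
        taper = np.clip(1.0 - steps / (blend_width + 1.0), 0.0, None)
        log_model = log_model + delta * taper
    mx[n_keep:] = np.exp(log_model)
    return RateSchedule(
        group_id=schedule.group_id, sex=schedule.sex, ages=ages, mx=mx, deaths=deaths
    )


def extend_rates(
    schedule: MortalitySchedule, config: ExtensionConfig
) -> tuple[RateSchedule, ExtensionFit]:
    """Select (or force) a family per the config and return spliced rates."""
    if config.family_override:
        fit = fit_extension_model(
            schedule, config.family_override, config.fit_window, config.max_age
        )
    else:
        fit = select_extension_model(
            schedule, config.families, config.fit_window, config.max_age
        )
    splice = config.resolved_splice()
    rates = extend_and_blend(schedule, fit, splice, config.max_age, config.blend_width)
    return rates, replace(fit, splice_age=splice)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class OldAgeExtension:
    """Model object wrapping candidate-family fitting and selection."""

    def __init__(self, schedule: MortalitySchedule, config: ExtensionConfig | None = None):
        self.schedule = schedule
        self.config = config or ExtensionConfig()

    def fit(self) -> "OldAgeExtensionResults":
        cfg = self.config
        if cfg.family_override:
            best = fit_extension_model(
                self.schedule, cfg.family_override, cfg.fit_window, cfg.max_age
            )
            table = pd.DataFrame(
                [{"family": best.family, "criterion": best.criterion_value,
                  "status": "forced", "params": best.params}]
            )
        else:
            best, table = select_extension_model(
                self.schedule, cfg.families, cfg.fit_window, cfg.max_age, return_table=True
            )
        return OldAgeExtensionResults(self, best, table)


class OldAgeExtensionResults:
    def __init__(self, model: OldAgeExtension, best: ExtensionFit, selection_table):
        self.model = model
        self.best = best
        self.selection_table = selection_table

    @property
    def family(self) -> str:
        return self.best.family

    @property
    def params(self) -> dict:
        return self.best.params

    def spliced_rates(self) -> RateSchedule:
        cfg = self.model.config
        return extend_and_blend(
            self.model.schedule, self.best, cfg.resolved_splice(), cfg.max_age,
            cfg.blend_width,
        )

    def summary(self) -> pd.DataFrame:
        return self.selection_table.copy()

    def plot(self, ax=None):
        """Observed vs fitted log mx diagnostic."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sched = self.model.schedule
        obs = sched.mx
        ok = np.isfinite(obs) & (obs > 0)
        ax.scatter(sched.ages[ok], np.log(obs[ok]), s=8, label="observed")
        lo = self.best.fit_window[0]
        grid = np.arange(lo, self.model.config.max_age + 1, dtype=float)
        ax.plot(grid, np.log(self.best.predict(grid)), label=f"fitted {self.family}")
        ax.set_xlabel("age")
        ax.set_ylabel("log mx")
        ax.legend()
        return ax
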