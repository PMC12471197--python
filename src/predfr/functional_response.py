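"""Functional-response classification and Holling disc-equation fitting.

The predation-trial design behind this module: a single predator is caged
with ``N`` prey (here *Lygus pratensis* nymphs or adults at densities
5-30 per bottle), and the number consumed ``Na`` after an exposure window
``T`` (1 day) is recorded over replicate bottles.

Analysis proceeds in two stages, following standard functional-response
practice:

1. **Type determination.** The proportion consumed ``Na/N`` is regressed on
   a cubic polynomial in ``N``; the sign of the linear coefficient ``b``
   determines the response type (``b < 0`` → Type II, decelerating;
   ``b > 0`` → Type III, sigmoid).

2. **Disc-equation fitting.** Holling's disc equation

   - Type II:  ``Na = a'TN / (1 + a'Th N)``
   - Type III: ``Na = a'TN^2 / (1 + a'Th N^2)``

   is fitted by nonlinear least squares for the instantaneous attack rate
   ``a'`` (per day) and handling time ``Th`` (days per prey).

From a fitted model the package derives the daily maximum predation rate
``T/Th``, the theoretical predation capacity ``a'/Th``, and the
density-dependent search efficiency ``S(N) = a' / (1 + a'Th N)``.
"""

from __future__ import annotations

import enum
import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    InvalidInputError,
    NoPredationError,
    UnderdeterminedError,
)

__all__ = [
    "PreyStage",
    "ResponseType",
    "PredationTrial",
    "TrialSet",
    "PolyTypeFit",
    "HollingFit",
    "SearchCurve",
    "DerivedMetrics",
    "holling_expectation",
    "fit_polynomial_type",
    "classify_expectation",
    "classify_response",
    "fit_holling",
    "predict_consumption",
    "derived_metrics",
    "search_efficiency",
    "rank_predators",
]

#: Lower bound imposed on both disc-equation parameters during optimisation.
PARAM_LOWER_BOUND = 1e-6


class PreyStage(str, enum.Enum):
    """Developmental stage of the prey offered in a trial."""

    NYMPH_4_5 = "nymph_4_5"
    ADULT = "adult"


class ResponseType(str, enum.Enum):
    """Functional-response type call from the sign of the cubic's linear term."""

    II = "II"
    III = "III"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PredationTrial:
    """One bottle-level observation: ``consumed`` of ``density`` prey eaten.

    Parameters
    ----------
    predator_id : str
        Predator taxon label (e.g. ``"O. sertatus"``).
    prey_stage : PreyStage
        Stage of the prey offered.
    density : int
        Initial prey density ``N`` (> 0).
    consumed : int | float
        Number of prey consumed ``Na`` within the exposure window. Real
        observations are integer counts; real-valued entries are allowed so
        per-density means and exact noise-free model expectations can flow
        through the same container.
    replicate : int
        Replicate bottle label.
    """

    predator_id: str
    prey_stage: PreyStage
    density: int
    consumed: float
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "prey_stage", PreyStage(self.prey_stage))
        if self.density <= 0:
            raise InvalidInputError(f"density must be positive, got {self.density}")
        if not 0 <= self.consumed <= self.density:
            raise InvalidInputError(
                f"consumed must lie in [0, density]: consumed={self.consumed}, "
                f"density={self.density}"
            )


@dataclass(frozen=True)
class TrialSet:
    """All replicate trials for one predator x prey-stage combination.

    ``exposure_T`` is the predator-prey exposure time in days (default one
    day). At least three distinct densities are required to identify the two
    disc-equation parameters with residual degrees of freedom.
    """

    predator_id: str
    prey_stage: PreyStage
    trials: tuple[PredationTrial, ...]
    exposure_T: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "prey_stage", PreyStage(self.prey_stage))
        object.__setattr__(self, "trials", tuple(self.trials))
        if not self.trials:
            raise InvalidInputError("TrialSet requires at least one trial")
        if self.exposure_T <= 0:
            raise InvalidInputError("exposure_T must be positive")
        for t in self.trials:
            if t.predator_id != self.predator_id or t.prey_stage != self.prey_stage:
                raise InvalidInputError(
                    "all trials in a TrialSet must share predator_id and prey_stage"
                )
        if len(set(t.density for t in self.trials)) < 3:
            raise UnderdeterminedError(
                "at least 3 distinct prey densities are required"
            )

    @property
    def densities(self) -> np.ndarray:
        return np.array([t.density for t in self.trials], dtype=float)

    @property
    def consumed(self) -> np.ndarray:
        return np.array([t.consumed for t in self.trials], dtype=float)

    @property
    def ratios(self) -> np.ndarray:
        """Per-trial proportion of offered prey consumed, ``Na/N``."""
        return self.consumed / self.densities

    def aggregate_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-density mean consumption, ``(densities, mean_consumed)``."""
        dens = np.unique(self.densities)
        means = np.array(
            [self.consumed[self.densities == d].mean() for d in dens]
        )
        return dens, means


@dataclass(frozen=True)
class PolyTypeFit:
    """Cubic fit of the consumption ratio and the resulting type call.

    Coefficients parameterise ``Na/N = a + bN + cN^2 + dN^3``; the type call
    is by the sign of ``b`` only. ``se_b`` is reported for context but never
    gates the classification.
    """

    a: float
    b: float
    c: float
    d: float
    se_b: float
    r_squared: float
    response_type: ResponseType

    def __post_init__(self) -> None:
        expected = classify_response(self.b)
        if expected is not self.response_type:
            raise InvalidInputError(
                f"response_type {self.response_type} inconsistent with sign of b={self.b}"
            )


@dataclass(frozen=True)
class HollingFit:
    """Disc-equation estimate for one predator x prey-stage combination.

    ``attack_rate`` is the instantaneous attack rate a' (per day);
    ``handling_time`` is Th in days per prey. ``converged`` is False when the
    optimiser failed or a parameter sits at its positivity bound; ``warnings``
    carries human-readable detail.
    """

    model: ResponseType
    attack_rate: float
    handling_time: float
    exposure_T: float
    r_squared: float
    n_points: int
    converged: bool = True
    predator_id: str = ""
    prey_stage: PreyStage | None = None
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.model not in (ResponseType.II, ResponseType.III):
            raise InvalidInputError("model must be II or III")
        if self.attack_rate <= 0 or self.handling_time <= 0:
            raise InvalidInputError("attack_rate and handling_time must be positive")
        if self.exposure_T <= 0:
            raise InvalidInputError("exposure_T must be positive")

    @property
    def daily_max_predation(self) -> float:
        """Upper bound on prey consumed in the exposure window, ``T/Th``."""
        return self.exposure_T / self.handling_time

    @property
    def theoretical_predation(self) -> float:
        """Control-potential index ``a'/Th``."""
        return self.attack_rate / self.handling_time


@dataclass(frozen=True)
class SearchCurve:
    """Search efficiency ``S(N) = a'/(1 + a'Th N)`` evaluated on a density grid."""

    densities: tuple[float, ...]
    efficiency: tuple[float, ...]
    source_fit: HollingFit


class DerivedMetrics(tuple):
    """``(daily_max_predation, theoretical_predation)`` with named access."""

    __slots__ = ()

    def __new__(cls, daily_max_predation: float, theoretical_predation: float):
        return super().__new__(cls, (daily_max_predation, theoretical_predation))

    @property
    def daily_max_predation(self) -> float:
        return self[0]

    @property
    def theoretical_predation(self) -> float:
        return self[1]


def holling_expectation(
    density,
    attack_rate: float,
    handling_time: float,
    exposure_T: float = 1.0,
    model: ResponseType | str = ResponseType.II,
):
    """Expected consumption under the disc equation (vectorised over density)."""
    model = ResponseType(model)
    n = np.asarray(density, dtype=float)
    if model is ResponseType.II:
        out = attack_rate * exposure_T * n / (1.0 + attack_rate * handling_time * n)
    elif model is ResponseType.III:
        n2 = n * n
        out = attack_rate * exposure_T * n2 / (1.0 + attack_rate * handling_time * n2)
    else:
        raise InvalidInputError("model must be II or III")
    return out if out.ndim else float(out)


def classify_response(b: float) -> ResponseType:
    """Type call from the cubic's linear coefficient: b<0 → II, b>0 → III.

    ``b == 0`` is indeterminate rather than forced to a type.
    """
    if not math.isfinite(b):
        raise InvalidInputError(f"b must be finite, got {b}")
    if b < 0:
        return ResponseType.II
    if b > 0:
        return ResponseType.III
    return ResponseType.INDETERMINATE


def fit_polynomial_type(trials: TrialSet, method: str = "ols") -> PolyTypeFit:
    """Fit the cubic type-determination polynomial to consumption ratios.

    ``method="ols"`` (default) is ordinary least squares of ``Na/N`` on
    ``(1, N, N^2, N^3)``. ``method="glm"`` instead fits a binomial
    logistic regression of the consumed/not-consumed counts on the same
    cubic predictor (the Juliano-style variant); the type call then uses
    the sign of the linear coefficient on the logit scale.

    Raises
    ------
    UnderdeterminedError
        Fewer than 4 distinct densities (cubic not identifiable).
    DegenerateDataError
        All ratios identically zero.
    """
    dens = trials.densities
    if len(np.unique(dens)) < 4:
        raise UnderdeterminedError(
            "fitting a cubic requires at least 4 distinct prey densities, "
            f"got {len(np.unique(dens))}"
        )
    ratios = trials.ratios
    if np.all(ratios == 0):
        raise DegenerateDataError("all consumption ratios are zero; nothing to fit")

    design = np.column_stack([np.ones_like(dens), dens, dens**2, dens**3])
    if method == "ols":
        return _cubic_ols(dens, ratios)
    elif method == "glm":
        endog = np.column_stack([trials.consumed, dens - trials.consumed])
        res = sm.GLM(endog, design, family=sm.families.Binomial()).fit()
        a_, b_, c_, d_ = (float(v) for v in res.params)
        se_b = float(res.bse[1])
        r2 = float(1.0 - res.deviance / res.null_deviance)
    else:
        raise InvalidInputError(f"unknown method {method!r}; use 'ols' or 'glm'")

    return PolyTypeFit(
        a=a_, b=b_, c=c_, d=d_, se_b=se_b, r_squared=r2,
        response_type=classify_response(b_),
    )


def _cubic_ols(dens: np.ndarray, ratios: np.ndarray) -> PolyTypeFit:
    design = np.column_stack([np.ones_like(dens), dens, dens**2, dens**3])
    res = sm.OLS(ratios, design).fit()
    a_, b_, c_, d_ = (float(v) for v in res.params)
    # a linear coefficient at floating-point noise level is genuinely zero
    # (constant-ratio data); snap it so the sign rule reads indeterminate
    if abs(b_) < 1e-10 * max(1.0, float(np.max(np.abs(ratios)))):
        b_ = 0.0
    fitted = design @ res.params
    sst = float(np.sum((ratios - ratios.mean()) ** 2))
    sse = float(np.sum((ratios - fitted) ** 2))
    return PolyTypeFit(
        a=a_, b=b_, c=c_, d=d_,
        se_b=float(res.bse[1]),
        r_squared=1.0 - sse / sst if sst > 0 else 1.0,
        response_type=classify_response(b_),
    )


def classify_expectation(
    attack_rate: float,
    handling_time: float,
    exposure_T: float = 1.0,
    model: ResponseType | str = ResponseType.II,
    densities: Sequence[float] = (5, 10, 15, 20, 25, 30),
) -> PolyTypeFit:
    """Type call the cubic procedure produces for a disc-equation truth.

    Evaluates the model's expected consumption ratio ``mu(N)/N`` on the
    design densities — without the availability clamp a finite bottle imposes
    — and runs the cubic OLS classification on those ratios. This isolates
    the classification procedure's behaviour on the response curve itself:
    at high attack rates the disc expectation can exceed the prey offered at
    low densities, and bottle data truncated at ``Na = N`` flatten there,
    which can perturb the sign of the fitted linear coefficient.
    """
    dens = np.asarray(list(densities), dtype=float)
    if len(np.unique(dens)) < 4:
        raise UnderdeterminedError(
            "fitting a cubic requires at least 4 distinct prey densities"
        )
    mu = holling_expectation(dens, attack_rate, handling_time, exposure_T, model)
    return _cubic_ols(dens, mu / dens)


def _initial_guess(trials: TrialSet, exposure_T: float) -> tuple[float, float]:
    """Low-density-slope / saturation heuristics for (a'0, Th0)."""
    dens = trials.densities
    cons = trials.consumed
    n_min = dens.min()
    slope = cons[dens == n_min].mean() / n_min / exposure_T
    a0 = max(slope, 10 * PARAM_LOWER_BOUND)
    th0 = 1.0 / max(cons.max(), 1.0)
    return a0, th0


def fit_holling(
    trials: TrialSet,
    model: ResponseType | str = ResponseType.II,
    exposure_T: float | None = None,
    aggregate: str = "raw",
) -> HollingFit:
    """Least-squares fit of the disc equation for (a', Th).

    Minimises ``sum((Na_obs - Na_model(N))^2)`` over ``(a', Th)`` with both
    parameters bounded below by a small positive constant. ``aggregate="raw"``
    fits every replicate bottle as a point; ``aggregate="mean"`` first
    collapses to per-density mean consumption.

    A parameter that finishes at its positivity bound (e.g. Th → 0 on
    perfectly linear, non-saturating data) is reported with
    ``converged=False`` and an explanatory warning rather than hidden.

    Raises
    ------
    NoPredationError
        Every trial recorded zero consumption.
    """
    model = ResponseType(model)
    if model not in (ResponseType.II, ResponseType.III):
        raise InvalidInputError("model must be II or III")
    T = trials.exposure_T if exposure_T is None else float(exposure_T)
    if T <= 0:
        raise InvalidInputError("exposure_T must be positive")

    if aggregate == "raw":
        dens, cons = trials.densities, trials.consumed
    elif aggregate == "mean":
        dens, cons = trials.aggregate_means()
    else:
        raise InvalidInputError(f"unknown aggregate {aggregate!r}; use 'raw' or 'mean'")

    if np.all(cons == 0):
        raise NoPredationError(
            f"all consumed counts are zero for {trials.predator_id}; "
            "the disc equation cannot be identified"
        )

    def residuals(params):
        a, th = params
        return holling_expectation(dens, a, th, T, model) - cons

    x0 = _initial_guess(trials, T)
    sol = least_squares(
        residuals,
        x0=x0,
        bounds=([PARAM_LOWER_BOUND, PARAM_LOWER_BOUND], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )

    a_hat, th_hat = float(sol.x[0]), float(sol.x[1])
    warns: list[str] = []
    converged = bool(sol.success)
    if not sol.success:
        warns.append(f"optimizer did not converge: {sol.message}")
    for name, val in (("attack_rate", a_hat), ("handling_time", th_hat)):
        if val <= 10 * PARAM_LOWER_BOUND:
            warns.append(f"{name} at lower positivity bound ({val:.2e})")
            converged = False
    if warns:
        _warnings.warn("; ".join(warns), RuntimeWarning, stacklevel=2)

    fitted = holling_expectation(dens, a_hat, th_hat, T, model)
    sst = float(np.sum((cons - cons.mean()) ** 2))
    sse = float(np.sum((cons - fitted) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0

    return HollingFit(
        model=model,
        attack_rate=a_hat,
        handling_time=th_hat,
        exposure_T=T,
        r_squared=r2,
        n_points=len(dens),
        converged=converged,
        predator_id=trials.predator_id,
        prey_stage=trials.prey_stage,
        warnings=tuple(warns),
    )


def predict_consumption(fit: HollingFit, density):
    """Expected consumption at ``density`` under the fitted disc equation.

    Monotone non-decreasing in density and bounded above by the daily
    maximum predation rate ``T/Th``.
    """
    n = np.asarray(density, dtype=float)
    if np.any(n < 0):
        raise InvalidInputError("density must be non-negative")
    return holling_expectation(
        density, fit.attack_rate, fit.handling_time, fit.exposure_T, fit.model
    )


def derived_metrics(fit: HollingFit) -> DerivedMetrics:
    """``(T/Th, a'/Th)``: daily maximum predation rate and theoretical predation.

    Values are returned at full precision; report layers round half-up to the
    published 2 decimal places.
    """
    if fit.handling_time <= 0:
        raise InvalidInputError("handling_time must be positive")
    return DerivedMetrics(
        fit.exposure_T / fit.handling_time,
        fit.attack_rate / fit.handling_time,
    )


def search_efficiency(fit: HollingFit, densities: Sequence[float]) -> SearchCurve:
    """Evaluate ``S(N) = a'/(1 + a'Th N)`` on a density grid.

    S declines monotonically with prey density and equals a' at N = 0.
    """
    dens = np.asarray(list(densities), dtype=float)
    if np.any(dens < 0):
        raise InvalidInputError("densities must be non-negative")
    s = fit.attack_rate / (1.0 + fit.attack_rate * fit.handling_time * dens)
    return SearchCurve(
        densities=tuple(float(d) for d in dens),
        efficiency=tuple(float(v) for v in s),
        source_fit=fit,
    )


def rank_predators(fits: Iterable[HollingFit]) -> list[HollingFit]:
    """Order fits by descending theoretical predation (a'/Th).

    Ties break by daily maximum predation rate, then lexicographically by
    predator label so the ordering is total and reproducible.
    """
    fits = list(fits)
    if not fits:
        raise InvalidInputError("rank_predators requires at least one fit")
    return sorted(
        fits,
        key=lambda f: (-f.theoretical_predation, -f.daily_max_predation, f.predator_id),
    )
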