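"""Bayesian MAP estimation of per-course kinetics from sparse plasma levels.

Each HD-MTX course contributes only a handful of timed plasma concentrations
(by protocol 24 h and 42 h, plus 48 h and 6-hourly samples when excretion is
delayed).  Two levels cannot identify four kinetic parameters, so estimation
is maximum-a-posteriori: the objective is

    -log posterior(theta) = -log likelihood(y | theta) - log prior(theta)

optimized over ``theta = log(V, ke, kcp, kpc)``.  The prior keeps the
distribution parameters near population values; the data pull clearance
(the well-identified functional ``ke*V``) toward the observed levels.

The interface follows the statsmodels convention: build a
:class:`CoursePKModel` from the data, call :meth:`~CoursePKModel.fit`, and
read estimates, uncertainties and diagnostics off the returned
:class:`CoursePKResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import pk
from .exceptions import InsufficientDataError, InvalidInputError
from .pk import InfusionSchedule, PKParameters, clearance_of

PARAM_NAMES = ("V", "ke", "kcp", "kpc")

#: Population initial estimates (mean +/- SD, original scale) used as priors:
#: V = 9.03 +/- 4.70 L/m^2, ke = 0.7 +/- 0.22 1/h, kcp = 0.08 +/- 0.050 1/h,
#: kpc = 0.11 +/- 0.0038 1/h.
DEFAULT_PRIOR_MEANS = {"V": 9.03, "ke": 0.7, "kcp": 0.08, "kpc": 0.11}
DEFAULT_PRIOR_SDS = {"V": 4.70, "ke": 0.22, "kcp": 0.050, "kpc": 0.0038}

#: Dose split (g/m^2) between the low-dose and high-dose model branches.
DOSE_BRANCH_SPLIT_G_M2 = 4.0
MAX_SAMPLE_TIME_H = 200.0


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior, moment-matched to an original-scale mean +/- SD.

    ``family`` selects how the prior density enters the MAP objective:

    - ``"lognormal"`` (default): log-parameters are Gaussian with
      ``sigma^2 = ln(1 + (sd/mean)^2)`` and ``mu = ln(mean) - sigma^2/2`` so
      that the original-scale mean and SD match the quoted values.  The MAP
      penalty is quadratic in ``theta = log x`` and the prior mode (in the
      optimized log parameterization) is ``exp(mu)``.
    - ``"normal"``: a Gaussian density on the original scale (mode = mean),
      still optimized over log-parameters to enforce positivity.
    """

    means: dict = field(default_factory=lambda: dict(DEFAULT_PRIOR_MEANS))
    sds: dict = field(default_factory=lambda: dict(DEFAULT_PRIOR_SDS))
    family: str = "lognormal"

    def __post_init__(self):
        if self.family not in ("lognormal", "normal"):
            raise InvalidInputError(f"unknown prior family {self.family!r}")
        for name in PARAM_NAMES:
            if name not in self.means or name not in self.sds:
                raise InvalidInputError(f"prior is missing parameter {name!r}")
            if self.means[name] <= 0 or self.sds[name] <= 0:
                raise InvalidInputError(f"prior mean/SD for {name!r} must be positive")

    def log_moments(self):
        """(mu, sigma) of the matched log-normal for each parameter."""
        m = np.array([self.means[k] for k in PARAM_NAMES])
        s = np.array([self.sds[k] for k in PARAM_NAMES])
        sigma2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        return mu, np.sqrt(sigma2)

    def mode(self) -> PKParameters:
        """Prior mode in the parameterization the optimizer uses."""
        if self.family == "lognormal":
            mu, _ = self.log_moments()
            values = np.exp(mu)
        else:
            values = np.array([self.means[k] for k in PARAM_NAMES])
        return PKParameters(*values)

    def neg_log_density(self, theta: np.ndarray) -> float:
        """-log prior at theta = log params, up to an additive constant."""
        if self.family == "lognormal":
            mu, sigma = self.log_moments()
            return float(np.sum(((theta - mu) / sigma) ** 2) / 2.0)
        m = np.array([self.means[k] for k in PARAM_NAMES])
        s = np.array([self.sds[k] for k in PARAM_NAMES])
        return float(np.sum(((np.exp(theta) - m) / s) ** 2) / 2.0)

    def with_overrides(self, means=None, sds=None) -> "PriorSpec":
        new_means = dict(self.means)
        new_sds = dict(self.sds)
        new_means.update(means or {})
        new_sds.update(sds or {})
        return replace(self, means=new_means, sds=new_sds)


@dataclass(frozen=True)
class ErrorModel:
    """Residual model for the assay: sd = proportional_cv * conc + floor (uM).

    A 10% proportional component with a small additive floor is the
    conventional description of immunoassay TDM error.  In the MAP objective
    the SD is evaluated at the *observed* concentration (fixed weights, the
    classic MAP-TDM convention), so the likelihood is an ordinary weighted
    sum of squares and vanishes entirely as the error SD grows.
    """

    proportional_cv: float = 0.10
    additive_floor_um: float = 0.05

    def __post_init__(self):
        if self.proportional_cv < 0 or self.additive_floor_um < 0:
            raise InvalidInputError("error model components must be non-negative")
        if self.proportional_cv == 0 and self.additive_floor_um == 0:
            raise InvalidInputError("error model must have positive dispersion")

    def sd_um(self, pred_um):
        return self.proportional_cv * np.asarray(pred_um) + self.additive_floor_um


@dataclass(frozen=True)
class ConcentrationSample:
    """One timed plasma level within a course.

    ``blq`` marks a sample below the quantitation limit; such samples carry
    the limit itself in ``conc_um`` and are excluded from the likelihood by
    default.
    """

    course: int
    time_h: float
    conc_um: float
    blq: bool = False

    def __post_init__(self):
        if self.time_h <= 0:
            raise InvalidInputError(f"sample time must be > 0 h, got {self.time_h}")
        if self.conc_um < 0:
            raise InvalidInputError(f"negative concentration {self.conc_um}")


def select_model_branch(actual_dose_g_m2: float) -> str:
    """Model branch keyed to the dose actually infused.

    Courses below 4 g/m^2 use the low-dose ("LR") branch prior set, courses at
    or above 4 g/m^2 the high-dose ("SHR") set.  Defaults are identical; the
    split exists so dose-reduced courses can be given their own priors.
    """
    if actual_dose_g_m2 <= 0:
        raise InvalidInputError(f"dose must be positive, got {actual_dose_g_m2}")
    return "SHR" if actual_dose_g_m2 >= DOSE_BRANCH_SPLIT_G_M2 else "LR"


#: Branch -> prior set.  Replace entries to differentiate the branches.
BRANCH_PRIORS = {"LR": PriorSpec(), "SHR": PriorSpec()}


class CoursePKModel:
    """MAP model for one HD-MTX course.

    Parameters
    ----------
    samples : sequence of ConcentrationSample
        At least two non-BLQ samples with times in (0, 200] h.
    schedule : InfusionSchedule
        The course's actual infusion (use :func:`hdmtx.pk.protocol_schedule`).
    prior : PriorSpec, optional
    error_model : ErrorModel, optional
    units : {"uM", "mg/L"}
        Unit of the supplied concentrations; converted internally to uM, so
        estimates are invariant to the choice.
    include_blq : bool
        If True, BLQ samples enter the likelihood at the quantitation limit
        (simple imputation); default False excludes them.
    """

    def __init__(
        self,
        samples: Sequence[ConcentrationSample],
        schedule: InfusionSchedule,
        prior: PriorSpec | None = None,
        error_model: ErrorModel | None = None,
        units: str = "uM",
        include_blq: bool = False,
    ):
        if units not in ("uM", "mg/L"):
            raise InvalidInputError(f"unknown units {units!r}")
        self.schedule = schedule
        self.prior = prior if prior is not None else PriorSpec()
        self.error_model = error_model if error_model is not None else ErrorModel()
        usable = [s for s in samples if include_blq or not s.blq]
        if len(usable) < 2:
            raise InsufficientDataError(
                f"MAP fit needs at least two usable plasma levels, got {len(usable)}"
            )
        times = np.array([s.time_h for s in usable])
        if (times > MAX_SAMPLE_TIME_H).any():
            raise InvalidInputError(f"sample times must be within (0, {MAX_SAMPLE_TIME_H}] h")
        conc = np.array([s.conc_um for s in usable])
        if units == "mg/L":
            conc = pk.mg_per_l_to_um(conc)
        self.times_h = times
        self.obs_um = conc
        self.n_samples = len(usable)
        # fixed observation weights: SD at the observed concentration
        self.sd_um = self.error_model.sd_um(self.obs_um)

    def predict_um(self, params: PKParameters, times=None):
        t = self.times_h if times is None else np.asarray(times, dtype=float)
        return pk.concentration(params, self.schedule, t, units="uM")

    def neg_log_posterior(self, theta: np.ndarray) -> float:
        """Objective: -log likelihood - log prior, both up to constants."""
        if np.any(np.abs(theta) > 50):
            return np.inf
        params = PKParameters(*np.exp(theta))
        pred = self.predict_um(params)
        nll = float(np.sum(0.5 * ((self.obs_um - pred) / self.sd_um) ** 2))
        return nll + self.prior.neg_log_density(theta)

    def _starts(self) -> np.ndarray:
        """Fixed deterministic multistart: prior mode and +/- one prior SD
        perturbations of log-V and log-ke."""
        mu, sigma = self.prior.log_moments()
        center = np.log(self.prior.mode().as_array())
        starts = [center]
        for i, name in enumerate(PARAM_NAMES[:2]):  # V, ke
            for sign in (+1.0, -1.0):
                s = center.copy()
                s[i] += sign * sigma[i]
                starts.append(s)
        return np.array(starts)

    def fit(self) -> "CoursePKResults":
        """Minimize the negative log posterior from the fixed multistart.

        The best objective wins; ties break toward the earlier start, so
        identical inputs always return bit-identical results.
        """
        best = None
        best_index = -1
        any_converged = False
        for i, x0 in enumerate(self._starts()):
            res = optimize.minimize(
                self.neg_log_posterior,
                x0,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
                best_index = i
        # derivative-free polish: L-BFGS-B's finite-difference gradient can
        # stall ~1% short of the optimum in the weakly identified directions
        polish = optimize.minimize(
            self.neg_log_posterior,
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if polish.fun <= best.fun:
            best = polish
        params = PKParameters(*np.exp(best.x))
        return CoursePKResults(
            model=self,
            params=params,
            theta=best.x.copy(),
            objective=float(best.fun),
            converged=any_converged,
            start_index=best_index,
        )


class CoursePKResults:
    """Estimates and diagnostics for one fitted course."""

    def __init__(self, model, params, theta, objective, converged, start_index,
                 branch: str = "SHR"):
        self.model = model
        self.params = params
        self.theta = theta
        self.objective = objective
        self.converged = converged
        self.start_index = start_index
        self.branch = branch
        self.n_samples = model.n_samples
        self._bse_log = None

    @property
    def clearance(self) -> float:
        """Estimated clearance, mL/min/m^2."""
        return clearance_of(self.params)

    @property
    def bse_log(self) -> np.ndarray:
        """Approximate posterior SDs of the log-parameters (Laplace: inverse
        numeric Hessian of the objective at the optimum)."""
        if self._bse_log is None:
            h = 1e-4
            n = len(self.theta)
            H = np.empty((n, n))
            f = self.model.neg_log_posterior
            f0 = f(self.theta)
            for i in range(n):
                for j in range(i, n):
                    ei = np.zeros(n); ei[i] = h
                    ej = np.zeros(n); ej[j] = h
                    H[i, j] = H[j, i] = (
                        f(self.theta + ei + ej) - f(self.theta + ei - ej)
                        - f(self.theta - ei + ej) + f(self.theta - ei - ej)
                    ) / (4 * h * h)
            try:
                cov = np.linalg.inv(H)
                var = np.diag(cov)
                self._bse_log = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
            except np.linalg.LinAlgError:
                self._bse_log = np.full(n, np.nan)
            _ = f0
        return self._bse_log

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald interval on the log scale, exponentiated."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.theta - z * self.bse_log)
        hi = np.exp(self.theta + z * self.bse_log)
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(PARAM_NAMES))

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "estimate": self.params.as_array(),
                "se_log": self.bse_log,
            },
            index=list(PARAM_NAMES),
        )
        df.loc["CL (mL/min/m2)"] = [self.clearance, np.nan]
        return df

    def __repr__(self):
        p = self.params
        return (
            f"<CoursePKResults CL={self.clearance:.1f} mL/min/m2 "
            f"V={p.V:.2f} ke={p.ke:.3f} kcp={p.kcp:.3f} kpc={p.kpc:.3f} "
            f"converged={self.converged}>"
        )


def fit_course(
    samples: Sequence[ConcentrationSample],
    schedule: InfusionSchedule,
    prior: PriorSpec | None = None,
    error_model: ErrorModel | None = None,
    dose_g_m2: float | None = None,
    **kwargs,
) -> CoursePKResults:
    """Functional entry point: build a :class:`CoursePKModel` and fit it.

    When ``dose_g_m2`` is given and no explicit prior is passed, the prior set
    is selected by the low/high-dose branch split at 4 g/m^2.
    """
    branch = "SHR"
    if dose_g_m2 is not None:
        branch = select_model_branch(dose_g_m2)
        if prior is None:
            prior = BRANCH_PRIORS[branch]
    result = CoursePKModel(samples, schedule, prior=prior, error_model=error_model,
                           **kwargs).fit()
    result.branch = branch
    if not result.converged:
        warnings.warn("MAP optimizer did not converge on any start; fit flagged",
                      stacklevel=2)
    return result


@dataclass(frozen=True)
class PatientPKSummary:
    """Per-patient averages across courses, with intra-patient variability.

    The coefficient of variation is 100 * SD / mean (sample SD, n-1
    denominator) across the patient's courses and is undefined (NaN) with a
    single course.
    """

    mean_level_24h_um: float
    mean_clearance: float
    cv_level_pct: float
    cv_clearance_pct: float
    n_courses: int


def _cv_pct(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    mean = np.mean(values)
    if mean == 0:
        return float("nan")
    return float(100.0 * np.std(values, ddof=1) / mean)


def summarize_patient(
    fits: Sequence[CoursePKResults],
    levels_24h_um: Sequence[float] | None = None,
) -> PatientPKSummary:
    """Aggregate converged course fits into the per-patient analysis unit.

    Parameters
    ----------
    fits : converged and non-converged course results; non-converged ones are
        dropped.  At least one converged fit is required.
    levels_24h_um : observed end-of-infusion levels per course, if available;
        falls back to model-predicted end-of-infusion levels otherwise.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise InsufficientDataError("no converged course fits to summarize")
    cl = np.array([f.clearance for f in usable])
    if levels_24h_um is not None and len(levels_24h_um) > 0:
        levels = np.asarray(levels_24h_um, dtype=float)
    else:
        levels = np.array(
            [f.model.predict_um(f.params, [f.model.schedule.end_of_infusion_h])[0]
             for f in usable]
        )
    return PatientPKSummary(
        mean_level_24h_um=float(np.mean(levels)),
        mean_clearance=float(np.mean(cl)),
        cv_level_pct=_cv_pct(levels),
        cv_clearance_pct=_cv_pct(cl),
        n_courses=len(usable),
    )
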