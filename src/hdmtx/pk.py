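"""Two-compartment forward model for a piecewise-constant HD-MTX infusion.

The model is the standard linear mammillary two-compartment system with
first-order elimination from the central compartment::

    dAc/dt = R(t) - (ke + kcp) * Ac + kpc * Ap
    dAp/dt = kcp * Ac - kpc * Ap
    C(t)   = Ac / V

where ``Ac``/``Ap`` are drug amounts (mg per m^2 body surface) in the central
and peripheral compartments, ``R(t)`` the infusion rate (mg/h/m^2), ``V`` the
apparent central volume (L/m^2) and the rate constants are in 1/h.  Clearance
is ``CL = ke * V``.  All quantities are per body-surface area; absolute BSA
never enters.

The protocol infusion delivers 10% of the dose as a loading segment over the
first 0.5 h and the remaining 90% over the following 23.5 h, so ``R(t)`` is
piecewise constant.  Within each constant-rate segment the system is affine
linear and solved exactly in the eigenbasis of the rate matrix, propagating
the compartment state across segment boundaries.  The internal concentration
unit is mg/L; micromolar output uses the methotrexate molar mass 454.44 g/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InvalidInputError

#: Molar mass of methotrexate, g/mol. Single conversion point mg/L <-> uM.
MTX_MOLAR_MASS = 454.44

#: Duration (h) and fraction of the loading segment of the protocol infusion.
LOADING_DURATION_H = 0.5
LOADING_FRACTION = 0.1
INFUSION_DURATION_H = 24.0


def mg_per_l_to_um(conc_mg_l):
    """Convert mg/L to umol/L (uM)."""
    return np.asarray(conc_mg_l, dtype=float) * 1000.0 / MTX_MOLAR_MASS


def um_to_mg_per_l(conc_um):
    """Convert umol/L (uM) to mg/L."""
    return np.asarray(conc_um, dtype=float) * MTX_MOLAR_MASS / 1000.0


@dataclass(frozen=True)
class PKParameters:
    """Kinetic state of one HD-MTX course.

    Parameters
    ----------
    V : float
        Apparent central volume of distribution, L/m^2.
    ke : float
        First-order elimination rate constant from the central compartment, 1/h.
    kcp : float
        Central-to-peripheral distribution rate constant, 1/h.
    kpc : float
        Peripheral-to-central return rate constant, 1/h.
    """

    V: float
    ke: float
    kcp: float
    kpc: float

    def __post_init__(self):
        for name in ("V", "ke", "kcp", "kpc"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise InvalidInputError(
                    f"PKParameters.{name} must be strictly positive, got {value!r}"
                )

    @property
    def clearance_l_per_h(self) -> float:
        """Central clearance CL = ke * V, in L/h/m^2."""
        return self.ke * self.V

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.ke, self.kcp, self.kpc])


def clearance_of(params: PKParameters) -> float:
    """Clearance in the reporting unit of therapeutic drug monitoring.

    CL = ke * V converted from L/h/m^2 to mL/min/m^2 (x1000 / 60).
    """
    return params.clearance_l_per_h * 1000.0 / 60.0


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion: ordered ``(start_h, end_h, rate_mg_h_m2)``.

    Segments must be contiguous from t=0 and their rate x duration must sum to
    the total dose (relative tolerance 1e-9).
    """

    dose_mg_m2: float
    segments: tuple = field(default=())

    def __post_init__(self):
        if self.dose_mg_m2 <= 0:
            raise InvalidInputError(f"dose must be positive, got {self.dose_mg_m2}")
        if not self.segments:
            raise InvalidInputError("schedule needs at least one segment")
        prev_end = 0.0
        total = 0.0
        for start, end, rate in self.segments:
            if not np.isclose(start, prev_end, rtol=0, atol=1e-12):
                raise InvalidInputError(
                    f"segments must be contiguous from 0; segment starts at {start}, "
                    f"previous ended at {prev_end}"
                )
            if end <= start:
                raise InvalidInputError(f"segment ({start}, {end}) has non-positive duration")
            if rate < 0:
                raise InvalidInputError(f"negative infusion rate {rate}")
            total += rate * (end - start)
            prev_end = end
        if abs(total - self.dose_mg_m2) > 1e-9 * self.dose_mg_m2:
            raise InvalidInputError(
                f"segment rates deliver {total} mg/m^2, expected {self.dose_mg_m2}"
            )

    @property
    def end_of_infusion_h(self) -> float:
        return self.segments[-1][1]


def protocol_schedule(dose_per_m2: float) -> InfusionSchedule:
    """Protocol infusion: 10% of the dose over 0.5 h, the rest over 23.5 h.

    Parameters
    ----------
    dose_per_m2 : float
        Total dose in mg/m^2 (5 g/m^2 courses pass 5000).
    """
    if dose_per_m2 <= 0:
        raise InvalidInputError(f"dose must be positive, got {dose_per_m2}")
    loading = LOADING_FRACTION * dose_per_m2 / LOADING_DURATION_H
    maintenance = (1.0 - LOADING_FRACTION) * dose_per_m2 / (
        INFUSION_DURATION_H - LOADING_DURATION_H
    )
    return InfusionSchedule(
        dose_mg_m2=dose_per_m2,
        segments=(
            (0.0, LOADING_DURATION_H, loading),
            (LOADING_DURATION_H, INFUSION_DURATION_H, maintenance),
        ),
    )


@dataclass(frozen=True)
class ConcentrationCurve:
    """Central-compartment concentration sampled on a time grid."""

    times_h: np.ndarray
    mg_per_l: np.ndarray

    @property
    def um(self) -> np.ndarray:
        return mg_per_l_to_um(self.mg_per_l)


def _decompose(params: PKParameters):
    """Closed-form eigendecomposition of the 2x2 compartment matrix.

    ``M = [[-a, kpc], [kcp, -kpc]]`` with ``a = ke + kcp`` has two real
    negative eigenvalues (the discriminant is strictly positive for positive
    rates).  Eigenvector for eigenvalue ``w`` is ``(kpc, w + a)``.

    Returns ``(w1, w2, P, Pinv)`` as plain floats / tuples; the scalar code
    path keeps the MAP inner loop fast.
    """
    a = params.ke + params.kcp
    b = params.kpc
    disc = np.sqrt((a - b) ** 2 + 4.0 * params.kcp * params.kpc)
    w1 = (-(a + b) - disc) / 2.0
    w2 = (-(a + b) + disc) / 2.0
    p11, p12 = b, b
    p21, p22 = w1 + a, w2 + a
    det = p11 * p22 - p12 * p21  # = kpc * (w2 - w1) = kpc * disc > 0
    i11, i12 = p22 / det, -p12 / det
    i21, i22 = -p21 / det, p11 / det
    return w1, w2, (p11, p12, p21, p22), (i11, i12, i21, i22)


def _phi(w: float, tau: float) -> float:
    """(exp(w*tau) - 1) / w, with the w -> 0 limit tau (stable via expm1)."""
    x = w * tau
    if abs(x) < 1e-12:
        return tau
    return np.expm1(x) / w


def _segment_boundaries(schedule: InfusionSchedule) -> list:
    """Segments plus a terminal zero-rate segment to +inf."""
    segs = list(schedule.segments)
    segs.append((schedule.end_of_infusion_h, np.inf, 0.0))
    return segs


def concentration(
    params: PKParameters,
    schedule: InfusionSchedule,
    times: Iterable[float] | float,
    units: str = "mg/L",
):
    """Central concentration at the requested times since infusion start.

    Exact per-segment solution: within a constant-rate segment the state obeys
    ``A(t0+tau) = P [exp(w tau) * alpha + phi(w, tau) * beta]`` where ``P, w``
    diagonalize the rate matrix, ``alpha = P^-1 A(t0)``, ``beta = P^-1 b`` and
    ``b = (R, 0)``.  ``phi`` handles the zero-eigenvalue limit so degenerate
    (nearly one-compartment) parameter sets remain well defined.

    Parameters
    ----------
    times : float or array-like
        Hours since infusion start; must be non-negative.
    units : {"mg/L", "uM"}

    Returns
    -------
    float or ndarray matching the shape of ``times``.
    """
    scalar = np.isscalar(times)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if (t < 0).any():
        raise InvalidInputError("times must be non-negative")
    if units not in ("mg/L", "uM"):
        raise InvalidInputError(f"unknown units {units!r}")

    w1, w2, (p11, p12, p21, p22), (i11, i12, i21, i22) = _decompose(params)
    exp = np.exp

    order = np.argsort(t, kind="stable")
    conc = np.empty_like(t)
    ac, ap = 0.0, 0.0  # amounts at the current segment start
    idx = 0
    n = t.size
    for start, end, rate in _segment_boundaries(schedule):
        a1 = i11 * ac + i12 * ap
        a2 = i21 * ac + i22 * ap
        b1 = i11 * rate
        b2 = i21 * rate
        # evaluate all requested times that fall in [start, end);
        # times exactly at a boundary land in the next segment (continuous).
        while idx < n and t[order[idx]] < end:
            tau = t[order[idx]] - start
            c1 = exp(w1 * tau) * a1 + _phi(w1, tau) * b1
            c2 = exp(w2 * tau) * a2 + _phi(w2, tau) * b2
            conc[order[idx]] = (p11 * c1 + p12 * c2) / params.V
            idx += 1
        if np.isinf(end):
            break
        tau = end - start
        c1 = exp(w1 * tau) * a1 + _phi(w1, tau) * b1
        c2 = exp(w2 * tau) * a2 + _phi(w2, tau) * b2
        ac = p11 * c1 + p12 * c2
        ap = p21 * c1 + p22 * c2
    # numerical noise can produce tiny negatives at t=0
    conc = np.where(np.abs(conc) < 1e-12, np.maximum(conc, 0.0), conc)
    if units == "uM":
        conc = mg_per_l_to_um(conc)
    return float(conc[0]) if scalar else conc


def amounts(params: PKParameters, schedule: InfusionSchedule, time_h: float):
    """Central and peripheral amounts (mg/m^2) at one time; used by mass-balance
    checks."""
    w1, w2, (p11, p12, p21, p22), (i11, i12, i21, i22) = _decompose(params)
    ac, ap = 0.0, 0.0
    for start, end, rate in _segment_boundaries(schedule):
        tau = min(time_h, end) - start
        if tau < 0:
            break
        a1 = i11 * ac + i12 * ap
        a2 = i21 * ac + i22 * ap
        b1 = i11 * rate
        b2 = i21 * rate
        c1 = np.exp(w1 * tau) * a1 + _phi(w1, tau) * b1
        c2 = np.exp(w2 * tau) * a2 + _phi(w2, tau) * b2
        ac = p11 * c1 + p12 * c2
        ap = p21 * c1 + p22 * c2
        if time_h < end:
            break
    return float(ac), float(ap)


def concentration_curve(
    params: PKParameters, schedule: InfusionSchedule, times: Sequence[float]
) -> ConcentrationCurve:
    """Convenience wrapper returning a :class:`ConcentrationCurve`."""
    t = np.asarray(times, dtype=float)
    return ConcentrationCurve(times_h=t, mg_per_l=np.asarray(concentration(params, schedule, t)))
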