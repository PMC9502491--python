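"""Structural pharmacokinetic models for oral nebivolol.

The workhorse is the two-compartment disposition model with first-order
absorption, an absorption lag time and linear elimination, parameterised by
apparent (oral) constants::

    tlag  lag time before absorption starts            [h]
    ka    first-order absorption rate constant         [1/h]
    cl    apparent clearance CL/F                      [10^3 L/h]
    v1    apparent central volume V1/F                 [10^3 L]
    q     apparent inter-compartmental clearance Q/F   [10^3 L/h]
    v2    apparent peripheral volume V2/F              [10^3 L]

Doses are given in mg and concentrations returned in ng/mL.  With volumes
carried in units of 10^3 L, ``amount / v1`` evaluates directly in ng/mL
(1 mg / 10^3 L = 1 ng/mL), which puts typical steady-state concentrations of
a 5 mg daily regimen near 1 ng/mL.  Bioavailability F is not modelled
separately: all parameters are apparent, i.e. already scaled by F, matching
oral-only data.

One-compartment and transit-absorption variants are provided for model
comparison.  Closed forms are used wherever the solution is a sum of
exponentials; the transit chain goes through a linear-ODE eigensolver.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PKParams",
    "MicroConstants",
    "DoseEvent",
    "Regimen",
    "micro_constants",
    "conc_single_dose",
    "conc_regimen",
    "interval_metrics",
    "parse_regimen",
    "REGIMEN_PRESETS",
]

#: relative threshold below which ka is considered numerically equal to a
#: disposition exponent (repeated-root degeneracy)
_KA_DEGENERACY_RTOL = 1e-8
#: relative perturbation applied to ka to lift the degeneracy
_KA_PERTURB = 1e-6

PARAM_NAMES = ("tlag", "ka", "cl", "v1", "q", "v2")


@dataclass(frozen=True)
class PKParams:
    """Apparent parameters of the two-compartment oral model.

    All six values must be strictly positive and finite.
    """

    tlag: float
    ka: float
    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"PKParams.{name} must be strictly positive and finite, got {value!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "PKParams":
        return cls(*(float(v) for v in values))

    def scaled(self, **factors: float) -> "PKParams":
        """Return a copy with selected fields multiplied by given factors."""
        values = {n: getattr(self, n) for n in PARAM_NAMES}
        for name, factor in factors.items():
            values[name] = values[name] * factor
        return PKParams(**values)


@dataclass(frozen=True)
class MicroConstants:
    """Micro rate constants and disposition exponents.

    Satisfies ``lambda1 + lambda2 == k10 + k12 + k21`` and
    ``lambda1 * lambda2 == k10 * k21`` with ``lambda1 > lambda2 > 0``.
    """

    k10: float
    k12: float
    k21: float
    lambda1: float
    lambda2: float


@dataclass(frozen=True)
class DoseEvent:
    """A single oral administration: ``amount`` mg at ``time`` h."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


@dataclass(frozen=True)
class Regimen:
    """A repeated-dose schedule: ``dose`` mg every ``interval`` h, ``n_doses`` times."""

    dose: float
    interval: float
    n_doses: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @classmethod
    def for_duration(cls, dose: float, interval: float, duration_h: float,
                     label: str = "") -> "Regimen":
        """Build the regimen covering ``duration_h`` hours of treatment.

        The number of doses is the smallest count whose dosing intervals
        cover the treatment duration (e.g. 15 days q24h -> 15 doses).
        """
        n = max(1, math.ceil(duration_h / interval))
        return cls(dose=dose, interval=interval, n_doses=n, label=label)

    def dose_events(self) -> list[DoseEvent]:
        return [DoseEvent(i * self.interval, self.dose) for i in range(self.n_doses)]

    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval

    @property
    def duration(self) -> float:
        """End of the final dosing interval, h."""
        return self.n_doses * self.interval


_REGIMEN_RE = re.compile(
    r"^\s*(?P<dose>\d+(?:\.\d+)?)\s*mg\s*q\s*(?P<interval>\d+(?:\.\d+)?)\s*h"
    r"\s*x\s*(?P<days>\d+(?:\.\d+)?)\s*d\s*$",
    re.IGNORECASE,
)


def parse_regimen(text: str) -> Regimen:
    """Parse a regimen string like ``"6mg q36h x15d"``."""
    m = _REGIMEN_RE.match(text)
    if m is None:
        raise ValueError(
            f"cannot parse regimen {text!r}; expected '<dose>mg q<interval>h x<days>d'"
        )
    dose = float(m.group("dose"))
    interval = float(m.group("interval"))
    days = float(m.group("days"))
    return Regimen.for_duration(dose, interval, 24.0 * days, label=text.strip())


#: The eight simulated nebivolol regimens, all covering 15 days of treatment.
REGIMEN_PRESETS: dict[str, Regimen] = {
    "5mg-qd": Regimen.for_duration(5.0, 24.0, 360.0, "5 mg qd"),
    "10mg-qd": Regimen.for_duration(10.0, 24.0, 360.0, "10 mg qd"),
    "20mg-qd": Regimen.for_duration(20.0, 24.0, 360.0, "20 mg qd"),
    "2.5mg-qd": Regimen.for_duration(2.5, 24.0, 360.0, "2.5 mg qd"),
    "2.5mg-bid": Regimen.for_duration(2.5, 12.0, 360.0, "2.5 mg BID"),
    "2.5mg-q6h": Regimen.for_duration(2.5, 6.0, 360.0, "2.5 mg q6h"),
    "6mg-q36h": Regimen.for_duration(6.0, 36.0, 360.0, "6 mg q36h"),
    "6mg-q48h": Regimen.for_duration(6.0, 48.0, 360.0, "6 mg q48h"),
}


def micro_constants(params: PKParams) -> MicroConstants:
    """Micro constants and disposition exponents of the two-compartment model.

    ``k10 = cl/v1``, ``k12 = q/v1``, ``k21 = q/v2``; the exponents are the
    roots of ``s^2 - (k10+k12+k21) s + k10*k21``, i.e. the (negated)
    eigenvalues of the disposition rate matrix.
    """
    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = math.sqrt(max(s * s - 4.0 * p, 0.0))
    lambda1 = 0.5 * (s + disc)
    lambda2 = p / lambda1 if lambda1 > 0 else 0.0  # product form: stable for small roots
    return MicroConstants(k10=k10, k12=k12, k21=k21, lambda1=lambda1, lambda2=lambda2)


def _resolve_ka(ka: float, lambda1: float, lambda2: float) -> float:
    """Perturb ka away from either disposition exponent if numerically equal."""
    for lam in (lambda1, lambda2):
        if abs(ka - lam) < _KA_DEGENERACY_RTOL * lam:
            return ka * (1.0 + _KA_PERTURB)
    return ka


def _biexp_coeffs(params: PKParams):
    """Macro coefficients of the triexponential oral solution.

    C(t') = dose*ka/v1 * (A1 e^{-l1 t'} + A2 e^{-l2 t'} + A3 e^{-ka t'}).
    """
    mc = micro_constants(params)
    l1, l2, k21 = mc.lambda1, mc.lambda2, mc.k21
    ka = _resolve_ka(params.ka, l1, l2)
    a1 = (k21 - l1) / ((ka - l1) * (l2 - l1))
    a2 = (k21 - l2) / ((ka - l2) * (l1 - l2))
    a3 = (k21 - ka) / ((l1 - ka) * (l2 - ka))
    return (l1, l2, ka), (a1, a2, a3)


def conc_single_dose(t, dose: float, params: PKParams):
    """Concentration (ng/mL) after one oral dose at time 0.

    Returns 0 for ``t <= tlag``; accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    (l1, l2, ka), (a1, a2, a3) = _biexp_coeffs(params)
    tp = np.maximum(t - params.tlag, 0.0)
    c = (dose * ka / params.v1) * (
        a1 * np.exp(-l1 * tp) + a2 * np.exp(-l2 * tp) + a3 * np.exp(-ka * tp)
    )
    c = np.where(t > params.tlag, np.maximum(c, 0.0), 0.0)
    return c if c.ndim else float(c)


def conc_regimen(t, regimen: Regimen, params: PKParams):
    """Concentration under a repeated-dose regimen by linear superposition."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    for ev in regimen.dose_events():
        mask = t >= ev.time
        if np.any(mask):
            out[mask] += conc_single_dose(t[mask] - ev.time, ev.amount, params)
    return out if out.ndim else float(out)


def interval_metrics(regimen: Regimen, params: PKParams, interval_index: int,
                     grid_step: float = 0.05) -> dict:
    """Peak/trough/average metrics over one dosing interval.

    ``interval_index`` counts intervals from 0; index ``n_doses - 1`` is the
    final interval of the course.  The profile is evaluated on a uniform grid
    of step ``grid_step`` h; ties in the maximum resolve to the earliest time.

    Returns a dict with ``cmax``, ``tmax`` (absolute time, h), ``cmin``,
    ``cavg`` (trapezoidal mean over the interval).
    """
    if not 0 <= interval_index < regimen.n_doses:
        raise ValueError(
            f"interval_index {interval_index} outside regimen with {regimen.n_doses} doses"
        )
    t0 = interval_index * regimen.interval
    t1 = t0 + regimen.interval
    n = max(int(round((t1 - t0) / grid_step)), 2)
    grid = np.linspace(t0, t1, n + 1)
    c = conc_regimen(grid, regimen, params)
    i_max = int(np.argmax(c))  # argmax returns the first maximum: earliest tmax
    cavg = float(np.trapezoid(c, grid) / (t1 - t0))
    return {
        "cmax": float(c[i_max]),
        "tmax": float(grid[i_max]),
        "cmin": float(np.min(c)),
        "cavg": cavg,
    }


# ---------------------------------------------------------------------------
# Vectorised kernels used by the estimation and trial-simulation machinery.
# Parameters arrive as an (n_subjects, 6) array in PARAM_NAMES order.
# ---------------------------------------------------------------------------

def _micro_arrays(params: np.ndarray):
    tlag, ka, cl, v1, q, v2 = (params[:, i] for i in range(6))
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    l1 = 0.5 * (s + disc)
    l2 = (k10 * k21) / l1
    # lift ka == lambda degeneracies
    for lam in (l1, l2):
        bad = np.abs(ka - lam) < _KA_DEGENERACY_RTOL * lam
        if np.any(bad):
            ka = np.where(bad, ka * (1.0 + _KA_PERTURB), ka)
    return tlag, ka, v1, k21, l1, l2


def conc_matrix(params: np.ndarray, dose_times: np.ndarray, dose_amounts: np.ndarray,
                obs_times: np.ndarray) -> np.ndarray:
    """Per-subject concentrations under individual dose histories.

    Parameters
    ----------
    params : (n, 6) array in ``PARAM_NAMES`` order.
    dose_times, dose_amounts : (n, d) arrays; pad unused slots with amount 0.
    obs_times : (n, m) array of evaluation times.

    Returns an (n, m) array of concentrations.
    """
    tlag, ka, v1, k21, l1, l2 = _micro_arrays(params)
    a1 = (k21 - l1) / ((ka - l1) * (l2 - l1))
    a2 = (k21 - l2) / ((ka - l2) * (l1 - l2))
    a3 = (k21 - ka) / ((l1 - ka) * (l2 - ka))
    scale = ka / v1

    # t' has shape (n, d, m)
    tp = obs_times[:, None, :] - dose_times[:, :, None] - tlag[:, None, None]
    active = tp > 0
    tp = np.where(active, tp, 0.0)
    terms = (
        a1[:, None, None] * np.exp(-l1[:, None, None] * tp)
        + a2[:, None, None] * np.exp(-l2[:, None, None] * tp)
        + a3[:, None, None] * np.exp(-ka[:, None, None] * tp)
    )
    contrib = np.where(active, terms, 0.0) * dose_amounts[:, :, None]
    return np.maximum(scale[:, None] * contrib.sum(axis=1), 0.0)


def final_interval_profiles(params: np.ndarray, regimen: Regimen,
                            grid_step: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Concentration profiles of many subjects over the final dosing interval.

    All doses precede the evaluated interval, so each exponential term
    accumulates into a per-subject geometric-type sum evaluated once; the cost
    is O(n_subjects * grid) rather than O(n_subjects * grid * n_doses).

    Returns ``(grid, conc)`` with ``grid`` shape (m,) and ``conc`` (n, m).
    """
    tlag, ka, v1, k21, l1, l2 = _micro_arrays(params)
    a1 = (k21 - l1) / ((ka - l1) * (l2 - l1))
    a2 = (k21 - l2) / ((ka - l2) * (l1 - l2))
    a3 = (k21 - ka) / ((l1 - ka) * (l2 - ka))
    scale = regimen.dose * ka / v1

    t0 = (regimen.n_doses - 1) * regimen.interval
    m = max(int(round(regimen.interval / grid_step)), 2)
    grid = t0 + np.linspace(0.0, regimen.interval, m + 1)
    td = regimen.dose_times()

    rel = grid - t0  # time since interval start, in [0, tau]
    conc = np.zeros((params.shape[0], grid.size))
    for lam, coef in ((l1, a1), (l2, a2), (ka, a3)):
        # sum_d exp(-lam*(t - td - tlag)) = exp(-lam*(t-t0)) * sum_d exp(lam*(td - t0 + tlag))
        w = np.exp(lam[:, None] * (td[None, :] - t0)).sum(axis=1)
        conc += (coef * w * np.exp(lam * tlag))[:, None] * np.exp(-lam[:, None] * rel[None, :])
    conc *= scale[:, None]
    # the final dose itself is still within its lag for rel <= tlag; recompute
    # those few leading grid columns through the generic superposition path
    ncols = int(np.searchsorted(rel, float(tlag.max()), side="right"))
    if ncols > 0:
        exact = _final_interval_exact(params, regimen, grid[:ncols])
        lag_mask = rel[None, :ncols] <= tlag[:, None]
        conc[:, :ncols] = np.where(lag_mask, exact, conc[:, :ncols])
    return grid, np.maximum(conc, 0.0)


def _final_interval_exact(params: np.ndarray, regimen: Regimen, grid: np.ndarray):
    dose_t = np.broadcast_to(regimen.dose_times(), (params.shape[0], regimen.n_doses))
    dose_a = np.full_like(dose_t, regimen.dose)
    return conc_matrix(params, dose_t, dose_a, np.broadcast_to(grid, (params.shape[0], grid.size)))


# ---------------------------------------------------------------------------
# Alternative structures (one-compartment; transit-chain absorption)
# ---------------------------------------------------------------------------

ONECPT_PARAM_NAMES = ("tlag", "ka", "cl", "v1")
TRANSIT_PARAM_NAMES = ("ktr", "ka", "cl", "v1", "q", "v2")
N_TRANSIT = 3  # fixed length of the transit chain


def conc_matrix_1cpt(params: np.ndarray, dose_times: np.ndarray,
                     dose_amounts: np.ndarray, obs_times: np.ndarray) -> np.ndarray:
    """One-compartment analogue of :func:`conc_matrix` (params (n, 4))."""
    tlag, ka, cl, v1 = (params[:, i] for i in range(4))
    k = cl / v1
    bad = np.abs(ka - k) < _KA_DEGENERACY_RTOL * k
    ka = np.where(bad, ka * (1.0 + _KA_PERTURB), ka)
    tp = obs_times[:, None, :] - dose_times[:, :, None] - tlag[:, None, None]
    active = tp > 0
    tp = np.where(active, tp, 0.0)
    kk = ka / (ka - k)
    terms = kk[:, None, None] * (
        np.exp(-k[:, None, None] * tp) - np.exp(-ka[:, None, None] * tp)
    )
    contrib = np.where(active, terms, 0.0) * dose_amounts[:, :, None]
    return np.maximum(contrib.sum(axis=1) / v1[:, None], 0.0)


def conc_matrix_transit(params: np.ndarray, dose_times: np.ndarray,
                        dose_amounts: np.ndarray, obs_times: np.ndarray) -> np.ndarray:
    """Transit-absorption two-compartment model (params (n, 6), ktr first).

    The dose passes through ``N_TRANSIT`` transit stages with shared rate
    ``ktr`` (replacing the lag time), is absorbed at rate ``ka`` into the
    central compartment, and disposes two-compartmentally.  The equal-rate
    chain makes the compartment matrix defective (repeated eigenvalue), so
    the linear system is propagated with the matrix exponential rather than
    an eigendecomposition.
    """
    from scipy.linalg import expm

    n = params.shape[0]
    out = np.zeros(obs_times.shape)
    for i in range(n):
        ktr, ka, cl, v1, q, v2 = params[i]
        nstate = N_TRANSIT + 3  # transit chain + depot + central + peripheral
        a = np.zeros((nstate, nstate))
        for j in range(N_TRANSIT):
            a[j, j] = -ktr
            a[j + 1, j] = ktr
        idep, icen, iper = N_TRANSIT, N_TRANSIT + 1, N_TRANSIT + 2
        a[idep, idep] -= ka
        a[icen, idep] += ka
        a[icen, icen] -= (cl + q) / v1
        a[iper, icen] += q / v1
        a[icen, iper] += q / v2
        a[iper, iper] -= q / v2
        # unique elapsed times across all doses for this subject
        tp_all = obs_times[i][None, :] - dose_times[i][:, None]
        uniq = np.unique(tp_all[tp_all > 0])
        central = {float(tp): expm(a * tp)[icen, 0] for tp in uniq}
        for d in range(dose_times.shape[1]):
            if dose_amounts[i, d] <= 0:
                continue
            for j in range(obs_times.shape[1]):
                tp = tp_all[d, j]
                if tp > 0:
                    out[i, j] += dose_amounts[i, d] * central[float(tp)] / v1
    return np.maximum(out, 0.0)


STRUCTURES = {
    "one_compartment": (ONECPT_PARAM_NAMES, conc_matrix_1cpt),
    "two_compartment": (PARAM_NAMES, conc_matrix),
    "transit": (TRANSIT_PARAM_NAMES, conc_matrix_transit),
}
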