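"""Non-compartmental analysis of individual concentration-time profiles.

Model-free summaries of a single profile: peak concentration and its time,
trapezoidal area under the curve to the last sample, terminal elimination
rate constant by log-linear regression, and the derived half-life
``t_half = ln 2 / kel``.

The terminal window for ``kel`` is chosen automatically as the contiguous
terminal run of at least three positive samples (excluding the peak) with
the best adjusted R^2 of the log-linear fit — standard NCA practice when no
window is pre-specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ConcentrationProfile", "NCAResult", "run_nca"]


@dataclass(frozen=True)
class ConcentrationProfile:
    """A single subject's sampled profile: strictly increasing times (h),
    non-negative concentrations (ng/mL)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if len(t) < 3:
            raise ValueError("NCA needs at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class NCAResult:
    """NCA summary; ``kel``/``t_half`` are None when no terminal fit exists."""

    cmax: float
    tmax: float
    auc_last: float
    kel: float | None
    t_half: float | None
    lambda_z_points: int = 0
    lambda_z_r2adj: float | None = None


def _auc_trapezoid(t: np.ndarray, c: np.ndarray) -> float:
    return float(np.trapezoid(c, t))


def _auc_linuplogdown(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down trapezoid: log interpolation on declining positive segments."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            auc += dt * 0.5 * (c0 + c1)
    return auc


def _terminal_fit(t: np.ndarray, c: np.ndarray, i_tmax: int, min_points: int = 3):
    """Best log-linear terminal fit over contiguous terminal windows.

    Candidate windows end at the last positive sample and start after tmax;
    the window with the highest adjusted R^2 (ties: more points) wins.
    Returns (kel, n_points, r2adj) or None.
    """
    pos = c > 0
    idx = np.arange(len(t))
    usable = idx[(idx > i_tmax) & pos]
    if len(usable) < min_points:
        return None
    # windows are terminal runs: suffixes of the usable index list
    best = None
    for start in range(0, len(usable) - min_points + 1):
        sel = usable[start:]
        slope, _, r, _, _ = stats.linregress(t[sel], np.log(c[sel]))
        n = len(sel)
        r2 = r * r
        r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if slope >= 0:
            continue
        if best is None or r2adj > best[2] + 1e-12 or (
            abs(r2adj - best[2]) <= 1e-12 and n > best[1]
        ):
            best = (-slope, n, r2adj)
    return best


def run_nca(profile: ConcentrationProfile, auc_method: str = "linear") -> NCAResult:
    """Run NCA on one profile.

    ``auc_method`` is ``"linear"`` (default) or ``"linuplogdown"``.  When
    fewer than three positive post-peak samples exist, ``kel`` and ``t_half``
    are reported missing while ``cmax``/``tmax``/``auc_last`` are still
    returned.  Ties in the maximum resolve to the earliest time.
    """
    t, c = profile.times, profile.concentrations
    i_tmax = int(np.argmax(c))  # first occurrence: earliest tmax on ties
    cmax = float(c[i_tmax])
    tmax = float(t[i_tmax])
    if auc_method == "linear":
        auc = _auc_trapezoid(t, c)
    elif auc_method == "linuplogdown":
        auc = _auc_linuplogdown(t, c)
    else:
        raise ValueError(f"unknown auc_method {auc_method!r}")
    fit = _terminal_fit(t, c, i_tmax)
    if fit is None:
        return NCAResult(cmax=cmax, tmax=tmax, auc_last=auc, kel=None, t_half=None)
    kel, n, r2adj = fit
    return NCAResult(cmax=cmax, tmax=tmax, auc_last=auc, kel=kel,
                     t_half=math.log(2) / kel, lambda_z_points=n,
                     lambda_z_r2adj=r2adj)
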