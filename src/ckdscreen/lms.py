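"""LMS (lambda-mu-sigma) growth-reference mathematics.

Age- and sex-specific reference distributions for BMI and systolic blood
pressure are represented in the LMS format: a Box-Cox power ``L``, a
median ``M`` and a coefficient of variation ``S`` per age.  A standard
deviation score (SDS, z-score) maps to a measurement value through

    value = M * (1 + L*S*z)**(1/L)     (L != 0)
    value = M * exp(S*z)               (L == 0)

Individuals keep their SDS for life and track their percentile as the
reference curves shift with age.  This module also fits LMS triplets from
tabulated percentiles and extends percentile curves past the last
tabulated age with a least-squares cubic polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtri

__all__ = [
    "LMSTriplet",
    "PercentileCurve",
    "value_from_sds",
    "sds_from_value",
    "extrapolate_poly3",
    "fit_lms_from_percentiles",
    "percentile_label_to_z",
]

_L_EPS = 1e-7  # |L| below this uses the log-normal (L=0) branch


@dataclass(frozen=True)
class LMSTriplet:
    """Box-Cox power ``L``, median ``M`` (> 0), coefficient of variation ``S`` (> 0)."""

    L: float
    M: float
    S: float

    def __post_init__(self):
        if not self.S > 0:
            raise ValueError(f"LMS S must be > 0, got {self.S}")
        if not self.M > 0:
            raise ValueError(f"LMS M must be > 0, got {self.M}")


@dataclass
class PercentileCurve:
    """Tabulated percentile values on an age grid.

    ``values`` has shape (n_ages, n_percentiles) and must be strictly
    increasing across percentiles at every age.
    """

    ages: np.ndarray
    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ages.size, len(self.labels)):
            raise ValueError("values must have shape (n_ages, n_percentiles)")
        bad = np.where(np.diff(self.values, axis=1) <= 0)[0]
        if bad.size:
            ages = sorted(set(self.ages[bad].tolist()))
            raise ValueError(f"percentiles not strictly increasing at ages {ages}")


def percentile_label_to_z(label: str) -> float:
    """Standard-normal quantile for a percentile label such as ``'P97'``."""
    if not label.upper().startswith("P"):
        raise ValueError(f"percentile label must look like 'P50', got {label!r}")
    pct = float(label[1:])
    if not 0 < pct < 100:
        raise ValueError(f"percentile must be in (0, 100), got {pct}")
    return float(ndtri(pct / 100.0))


def value_from_sds(t: LMSTriplet, z):
    """Measurement value at SDS ``z`` under the reference ``t``."""
    z = np.asarray(z, dtype=float)
    if abs(t.L) < _L_EPS:
        out = t.M * np.exp(t.S * z)
    else:
        arg = 1.0 + t.L * t.S * z
        if np.any(arg <= 0):
            bad = np.atleast_1d(z)[np.atleast_1d(arg) <= 0]
            raise ValueError(f"SDS out of the Box-Cox domain (1+L*S*z <= 0) at z={bad[:5]}")
        out = t.M * arg ** (1.0 / t.L)
    return out if out.shape else float(out)


def sds_from_value(t: LMSTriplet, x):
    """Inverse of :func:`value_from_sds`."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("measurement values must be positive")
    if abs(t.L) < _L_EPS:
        out = np.log(x / t.M) / t.S
    else:
        out = ((x / t.M) ** t.L - 1.0) / (t.L * t.S)
    return out if out.shape else float(out)


def value_from_sds_arrays(L, M, S, z, clip_domain: bool = False):
    """Vectorized :func:`value_from_sds` with per-element LMS parameters.

    With ``clip_domain`` the Box-Cox argument is floored just above zero
    instead of raising; used for population-scale draws where z is
    already truncated to a safe range.
    """
    L, M, S, z = np.broadcast_arrays(*map(np.asarray, (L, M, S, z)))
    arg = 1.0 + L * S * z
    if np.any(arg <= 0):
        if not clip_domain:
            raise ValueError("SDS out of the Box-Cox domain (1+L*S*z <= 0)")
        arg = np.maximum(arg, 1e-8)
    near0 = np.abs(L) < _L_EPS
    Lsafe = np.where(near0, 1.0, L)
    out = np.where(near0, M * np.exp(S * z), M * arg ** (1.0 / Lsafe))
    return out


def sds_from_value_arrays(L, M, S, x):
    """Vectorized :func:`sds_from_value` with per-element LMS parameters."""
    L, M, S, x = np.broadcast_arrays(*map(np.asarray, (L, M, S, x)))
    if np.any(x <= 0):
        raise ValueError("measurement values must be positive")
    near0 = np.abs(L) < _L_EPS
    Lsafe = np.where(near0, 1.0, L)
    out = np.where(
        near0,
        np.log(x / M) / S,
        ((x / M) ** Lsafe - 1.0) / (Lsafe * S),
    )
    return out


def _poly3_extend(ages: np.ndarray, series: np.ndarray, target_ages: np.ndarray) -> np.ndarray:
    """Least-squares cubic in age, evaluated on ``target_ages``."""
    if np.unique(ages).size < 4:
        raise ValueError("cubic extrapolation needs >= 4 distinct ages")
    # centre the age axis for conditioning
    mid = ages.mean()
    coef = np.polynomial.polynomial.polyfit(ages - mid, series, deg=3)
    return np.polynomial.polynomial.polyval(np.asarray(target_ages, float) - mid, coef)


def extrapolate_poly3(curve: PercentileCurve, target_ages) -> PercentileCurve:
    """Fit each percentile series with a cubic in age and evaluate on ``target_ages``.

    Used both to interpolate references tabulated in 5-year age groups
    onto integer ages and to extend references ending at age 79 up to 90.
    Raises if the extrapolated percentiles cross.
    """
    target_ages = np.asarray(target_ages, dtype=float)
    out = np.column_stack(
        [_poly3_extend(curve.ages, curve.values[:, j], target_ages) for j in range(len(curve.labels))]
    )
    if np.any(np.diff(out, axis=1) <= 0):
        bad = np.where(np.diff(out, axis=1) <= 0)[0]
        ages = sorted(set(target_ages[bad].tolist()))
        raise ValueError(f"extrapolated percentiles cross at ages {ages}")
    return PercentileCurve(ages=target_ages, labels=list(curve.labels), values=out)


def fit_lms_from_percentiles(labels: list[str], values) -> LMSTriplet:
    """Recover the LMS triplet whose quantiles best match tabulated percentiles.

    Minimizes squared error between ``value_from_sds((L, M, S), z_label)``
    and the tabulated values; with exactly three percentile points the fit
    is exact to solver tolerance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 percentile points")
    if np.any(np.diff(values) <= 0):
        raise ValueError("percentile values must be strictly increasing")
    z = np.array([percentile_label_to_z(lab) for lab in labels])
    order = np.argsort(z)
    z, values = z[order], values[order]

    # initial guess: median from the point closest to P50, S from spread
    m0 = float(np.interp(0.0, z, values))
    s0 = float(np.clip((values[-1] - values[0]) / (m0 * (z[-1] - z[0])), 1e-3, 1.0))

    def resid(theta):
        L, logM, logS = theta
        M, S = np.exp(logM), np.exp(logS)
        arg = 1.0 + L * S * z
        if np.any(arg <= 0):
            return np.full_like(z, 1e6)
        if abs(L) < _L_EPS:
            pred = M * np.exp(S * z)
        else:
            pred = M * arg ** (1.0 / L)
        return pred - values

    sol = least_squares(resid, x0=[1.0, np.log(m0), np.log(s0)], xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise RuntimeError(f"LMS fit did not converge: {sol.message}")
    L, logM, logS = sol.x
    return LMSTriplet(L=float(L), M=float(np.exp(logM)), S=float(np.exp(logS)))
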