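"""Robust dispersion estimators and distribution tests.

Landmark digitisation errors are strongly right-skewed, so dispersion is
summarised with the median, the normalised median absolute deviation (NMAD)
and the square root of the biweight midvariance (BWMV) rather than the
standard deviation.  NMAD = 1.4826 * MAD, the constant approximating
1/Phi^-1(3/4) so that NMAD estimates sigma for Gaussian data; BWMV is a
robust *and* efficient variance estimator that zero-weights points more
than 9 MADs from the median and smoothly down-weights the rest with Tukey
biweights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Literal normalisation constant of the MAD, as conventionally printed
#: (4-decimal rounding of 1/Phi^-1(0.75)).
NMAD_CONSTANT = 1.4826


def _as_sample(x, min_n: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"sample must contain at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    return x


def mad(x) -> float:
    """Median of absolute deviations from the sample median.

    Even-length medians are the mean of the central pair (numpy convention).
    """
    x = _as_sample(x)
    return float(np.median(np.abs(x - np.median(x))))


def nmad(x) -> float:
    """Normalised MAD: ``1.4826 * mad(x)``, a robust sigma estimate."""
    return NMAD_CONSTANT * mad(x)


def biweight_midvariance(x) -> float:
    """Tukey biweight midvariance.

    With m the sample median and U_i = (x_i - m) / (9 MAD), observations
    with \\|U_i\\| >= 1 get zero weight and

        BWMV = n * sum a_i (x_i - m)^2 (1 - U_i^2)^4
               / (sum a_i (1 - U_i^2)(1 - 5 U_i^2))^2.

    Returns 0.0 for degenerate samples with MAD = 0 (all mass at the
    median), where the estimator is undefined.
    """
    x = _as_sample(x, min_n=2)
    n = x.size
    m = np.median(x)
    s = mad(x)
    if s == 0.0:
        return 0.0
    u = (x - m) / (9.0 * s)
    a = np.abs(u) < 1.0
    num = n * np.sum(a * (x - m) ** 2 * (1 - u**2) ** 4)
    den = np.sum(a * (1 - u**2) * (1 - 5 * u**2)) ** 2
    return float(num / den)


def sqrt_bwmv(x) -> float:
    """Square root of the biweight midvariance (the reported scale)."""
    return float(np.sqrt(biweight_midvariance(x)))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank H with tie correction; chi^2 p on g-1 dof."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [_as_sample(g) for g in groups]
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError as exc:  # all values identical across groups
        if "identical" in str(exc):
            return 0.0, 1.0
        raise
    return float(h), float(p)


def normality_test(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p."""
    x = _as_sample(x, min_n=3)
    w, p = stats.shapiro(x)
    return float(w), float(p)


def skewness(x) -> float:
    """Adjusted Fisher-Pearson skewness; 0.0 for constant samples."""
    x = _as_sample(x, min_n=2)
    if np.ptp(x) == 0.0:
        return 0.0
    return float(stats.skew(x, bias=False))


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie handling."""
    x = _as_sample(x, min_n=2)
    y = _as_sample(y, min_n=2)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Kendall's tau is undefined for constant input")
    tau, p = stats.kendalltau(x, y)
    return float(tau), float(p)


@dataclass(frozen=True)
class RobustSummary:
    """Table-style dispersion summary of one error sample (mm)."""

    n: int
    min: float
    mean: float
    sd: float
    median: float
    nmad: float
    sqrt_bwmv: float
    max: float

    @classmethod
    def from_values(cls, x) -> "RobustSummary":
        x = _as_sample(x)
        return cls(
            n=int(x.size),
            min=float(np.min(x)),
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
            median=float(np.median(x)),
            nmad=nmad(x),
            sqrt_bwmv=sqrt_bwmv(x) if x.size > 1 else 0.0,
            max=float(np.max(x)),
        )
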