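"""Benford first-digit conformance testing of centrality distributions.

Benford's law states that the first significant digit f of a quantity
spanning several orders of magnitude follows P(f) = log10(1 + 1/f).  Deviation
of a centrality's first-digit distribution from this law is used as a
data-quality signal.  Three distances are reported: Pearson's chi-squared
statistic (used as a distance, no p-value attached), the 1-D Wasserstein
(earth-mover) distance on the ordered digit support with unit ground
distance, and the sum of squared deviations between the proportion vectors.

Zero and non-finite values carry no significand, so they are excluded from
digit extraction; the exclusion count is reported for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DIGITS = np.arange(1, 10)


class EmptySampleError(ValueError):
    """No positive finite values to test."""


def benford_pmf() -> np.ndarray:
    """Theoretical first-digit proportions P(f) = log10(1 + 1/f), f=1..9."""
    return np.log10(1.0 + 1.0 / DIGITS)


def first_digit(x: float) -> int:
    """First significant decimal digit of a positive finite number.

    Computed by scaling with powers of ten (never by string formatting).
    Raises ``ValueError`` for non-positive or non-finite input.
    """
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"first digit undefined for {x!r}")
    # initial guess from log10, then correct for floating-point slop
    e = math.floor(math.log10(x))
    y = x / 10.0 ** e
    while y < 1.0:
        y *= 10.0
    while y >= 10.0:
        y /= 10.0
    return int(y)


@dataclass
class BenfordReport:
    digit_counts: np.ndarray
    n_used: int
    n_excluded_zero_or_nonfinite: int
    p_observed: np.ndarray
    p_benford: np.ndarray
    chi2: float
    wasserstein: float
    ssd: float
    qq_points: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "digit_counts": self.digit_counts.tolist(),
            "n_used": self.n_used,
            "n_excluded_zero_or_nonfinite": self.n_excluded_zero_or_nonfinite,
            "p_observed": self.p_observed.tolist(),
            "p_benford": self.p_benford.tolist(),
            "chi2": self.chi2,
            "wasserstein": self.wasserstein,
            "ssd": self.ssd,
            "qq_points": [list(p) for p in self.qq_points],
        }


def benford_test(values) -> BenfordReport:
    """First-digit test of a sample (array-like or CentralityTable).

    chi2        = sum_f (O_f - n p_f)^2 / (n p_f)
    wasserstein = sum_k |CDF_obs(k) - CDF_benford(k)|   (unit ground distance)
    ssd         = sum_f (O_f/n - p_f)^2
    """
    if hasattr(values, "values") and isinstance(getattr(values, "values"), dict):
        arr = np.array(list(values.values.values()), dtype=float)
    else:
        arr = np.asarray(values, dtype=float).ravel()
    usable = arr[np.isfinite(arr) & (arr > 0)]
    n_excluded = arr.size - usable.size
    if usable.size == 0:
        raise EmptySampleError("no positive finite values to test")

    digits = np.array([first_digit(float(v)) for v in usable])
    counts = np.bincount(digits, minlength=10)[1:10].astype(np.int64)
    n = int(counts.sum())
    p_obs = counts / n
    p_ben = benford_pmf()

    expected = n * p_ben
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    cdf_obs = np.cumsum(p_obs)
    cdf_ben = np.cumsum(p_ben)
    wasserstein = float(np.sum(np.abs(cdf_obs - cdf_ben)))
    ssd = float(np.sum((p_obs - p_ben) ** 2))
    qq = [(float(tb), float(to)) for tb, to in zip(cdf_ben, cdf_obs)]

    return BenfordReport(
        digit_counts=counts,
        n_used=n,
        n_excluded_zero_or_nonfinite=int(n_excluded),
        p_observed=p_obs,
        p_benford=p_ben,
        chi2=chi2,
        wasserstein=wasserstein,
        ssd=ssd,
        qq_points=qq,
    )
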