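"""Power-law fitting of degree (and other centrality) distributions.

Implements the Clauset–Shalizi–Newman procedure: maximum-likelihood estimation
of the exponent alpha of P(x) ~ x^-alpha above a lower cutoff xmin, with xmin
chosen by minimising the Kolmogorov–Smirnov distance between the empirical
tail and the fitted model.  Both the discrete (zeta-normalised) and the
continuous (Pareto) forms are provided; degree distributions use the discrete
form since degrees are integers.

Also provides ``loglog_slope``, the ordinary least-squares slope of a
log-binned histogram on log–log axes — the naive "distribution slope" some
robustness analyses compare — and an exact discrete power-law sampler for
synthetic data and estimator-consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

MIN_SAMPLE = 10
MIN_TAIL = 10


class DegenerateSampleError(ValueError):
    """All observations identical: no spread to fit a power law to."""


@dataclass
class PowerLawFit:
    alpha: float
    xmin: float
    ks_distance: float
    n_tail: int
    discrete: bool
    small_tail_warning: bool = False

    def __repr__(self) -> str:  # compact, matches typical fit-report style
        return (
            f"PowerLawFit(alpha={self.alpha:.4f}, xmin={self.xmin:g}, "
            f"ks={self.ks_distance:.4f}, n_tail={self.n_tail}, "
            f"discrete={self.discrete})"
        )


# ---------------------------------------------------------------------------
# likelihood / CDF machinery
# ---------------------------------------------------------------------------

def _discrete_alpha_mle(tail: np.ndarray, xmin: int) -> float:
    """Maximise the zeta-normalised log-likelihood over alpha in (1, 20]."""
    slog = float(np.log(tail).sum())
    n = tail.size

    def negll(alpha: float) -> float:
        return n * float(np.log(special.zeta(alpha, xmin))) + alpha * slog

    res = optimize.minimize_scalar(negll, bounds=(1.0001, 20.0), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def _continuous_alpha_mle(tail: np.ndarray, xmin: float) -> float:
    return 1.0 + tail.size / float(np.log(tail / xmin).sum())


def _ks_discrete(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, int(tail.max()) + 1)
    z = special.zeta(alpha, xmin)
    # model survival P(X >= x) = zeta(alpha, x) / zeta(alpha, xmin)
    model_cdf = 1.0 - special.zeta(alpha, xs + 1) / z
    emp_cdf = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def _ks_continuous(tail: np.ndarray, alpha: float, xmin: float) -> float:
    xs = np.sort(tail)
    model_cdf = 1.0 - (xs / xmin) ** (1.0 - alpha)
    emp_hi = np.arange(1, xs.size + 1) / xs.size
    emp_lo = np.arange(0, xs.size) / xs.size
    return float(max(np.max(np.abs(emp_hi - model_cdf)),
                     np.max(np.abs(emp_lo - model_cdf))))


def fit_power_law(
    values, *, discrete: bool | None = None, xmin: float | None = None
) -> PowerLawFit:
    """Fit P(x) ~ x^-alpha by MLE with KS-minimising xmin selection.

    Parameters
    ----------
    values : array-like of positive numbers (>= 10 of them)
    discrete : fit the zeta-normalised discrete model; inferred from the data
        (all values integral) when None
    xmin : fix the lower cutoff instead of scanning; when None, every unique
        value is tried and the xmin with the smallest KS distance wins, ties
        broken toward smaller xmin

    A fit whose tail holds fewer than 10 points carries
    ``small_tail_warning=True`` rather than failing.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    if arr.size < MIN_SAMPLE:
        raise ValueError(f"need at least {MIN_SAMPLE} positive values, got {arr.size}")
    if np.all(arr == arr[0]):
        raise DegenerateSampleError("all values are identical")
    if discrete is None:
        discrete = bool(np.all(arr == np.round(arr)))

    def fit_at(xm: float) -> tuple[float, float, int]:
        tail = arr[arr >= xm]
        if discrete:
            xm_i = int(round(xm))
            alpha = _discrete_alpha_mle(tail, xm_i)
            ks = _ks_discrete(tail, alpha, xm_i)
        else:
            alpha = _continuous_alpha_mle(tail, xm)
            ks = _ks_continuous(tail, alpha, xm)
        return alpha, ks, tail.size

    if xmin is not None:
        alpha, ks, n_tail = fit_at(float(xmin))
        return PowerLawFit(alpha, float(xmin), ks, n_tail, discrete,
                           small_tail_warning=n_tail < MIN_TAIL)

    candidates = np.unique(arr)
    # a candidate must leave >= 2 distinct tail values for the MLE to exist
    candidates = candidates[candidates < candidates[-1]]
    if candidates.size > 512:  # keep the xmin scan tractable on large samples
        qs = np.quantile(candidates, np.linspace(0, 1, 512))
        candidates = np.unique(
            candidates[np.searchsorted(candidates, qs, side="left").clip(0, candidates.size - 1)]
        )
    if candidates.size == 0:
        raise DegenerateSampleError("no viable xmin candidates")
    best: tuple[float, float, float, int] | None = None  # (ks, xmin, alpha, n)
    for xm in candidates:
        alpha, ks, n_tail = fit_at(float(xm))
        if n_tail < 2:
            continue
        if best is None or ks < best[0] - 1e-12:  # ties -> smaller xmin
            best = (ks, float(xm), alpha, n_tail)
    assert best is not None
    ks, xm, alpha, n_tail = best
    return PowerLawFit(alpha, xm, ks, n_tail, discrete,
                       small_tail_warning=n_tail < MIN_TAIL)


# ---------------------------------------------------------------------------
# log-log histogram slope
# ---------------------------------------------------------------------------

def loglog_slope(values, n_bins: int = 15) -> float:
    """OLS slope of log10(count density) vs log10(value) on log-spaced bins.

    Counts are divided by bin width, so an exact power-law P(x) ~ x^-alpha
    yields a slope of approximately -alpha.  Raises ``ValueError`` when fewer
    than two non-empty bins exist.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr) & (arr > 0)]
    if arr.size == 0:
        raise ValueError("no positive values")
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        raise ValueError("single-bin histogram: slope undefined")
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[-1] *= 1 + 1e-12  # include the max
    counts, _ = np.histogram(arr, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = counts > 0
    if mask.sum() < 2:
        raise ValueError("fewer than two non-empty bins: slope undefined")
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / widths[mask])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# exact discrete power-law sampler
# ---------------------------------------------------------------------------

def sample_discrete_powerlaw(
    alpha: float,
    size: int,
    rng: np.random.Generator,
    *,
    xmin: int = 1,
    xmax: int = 1_000_000,
) -> np.ndarray:
    """Draw from P(X = x) = x^-alpha / zeta(alpha, xmin), x in [xmin, xmax].

    Inverse-CDF sampling on the explicitly normalised pmf; the truncation mass
    beyond xmax is O(xmax^(1-alpha)) and folded into the last atom.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    xs = np.arange(xmin, xmax + 1, dtype=float)
    pmf = xs ** (-alpha)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(size)
    idx = np.searchsorted(cdf, u, side="left")
    return (idx + xmin).astype(np.int64)
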