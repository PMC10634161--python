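"""Friedman's variable-span super smoother and smoothed-maximum selection.

The super smoother combines running local-linear fits at three spans —
0.05 (tweeter), 0.2 (midrange) and 0.5 (woofer) of the series length —
using leave-one-out cross-validated absolute residuals to pick the best
span at each point.  The per-point span choice is itself smoothed with the
midrange span, the final value is interpolated between the two bracketing
span smooths, and one last tweeter-span pass removes interpolation
artefacts.  A ``bass`` parameter in [0, 10] biases the span choice toward
the woofer (smoother) end.

Windows are symmetric nearest-neighbour windows truncated at the
boundaries, so local-linear fits reproduce affine data exactly everywhere.

Applied to an incremental-selection accuracy curve, the smoother turns the
noisy per-count R^2 values into a robust trend whose maximum gives the
optimal number of SNPs; smoothing prevents an isolated noise spike from
being mistaken for the optimum.  By default the curve is smoothed against
log10 of the SNP count, matching the roughly geometric spacing of the
schedule at the high end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import IfsgpError
from .ifs_core import IfsCurve

SPANS = (0.05, 0.2, 0.5)  # tweeter, midrange, woofer


@dataclass
class SmoothedCurve:
    """A smoothed accuracy curve aligned with the raw IFS curve points."""

    snp_counts: np.ndarray
    smoothed_r2: np.ndarray
    span_used: np.ndarray


@dataclass
class SelectionResult:
    """The smoothed-maximum choice of SNP count.

    ``use_all_snps`` is true iff the optimum is the final (all-SNP) point;
    ``selected_snp_ids`` is filled by the evaluation stage once a final
    ranking is available.
    """

    optimal_count: int
    optimal_smoothed_r2: float
    use_all_snps: bool
    smoothed: SmoothedCurve
    selected_snp_ids: list[str] | None = None


def _running_linear(
    x: np.ndarray, y: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Local-linear smooth over symmetric nearest-neighbour windows.

    Returns (fit, loo_residual) where the leave-one-out residual is the
    exact deleted residual (y_i - fit_i) / (1 - h_ii) of the local fit.
    """
    n = len(x)
    window = max(2, min(window, n))
    half = window // 2

    cum1 = np.concatenate(([0.0], np.cumsum(np.ones(n))))
    cumx = np.concatenate(([0.0], np.cumsum(x)))
    cumy = np.concatenate(([0.0], np.cumsum(y)))
    cumxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cumxy = np.concatenate(([0.0], np.cumsum(x * y)))

    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n - 1, i + half)

    m = cum1[hi + 1] - cum1[lo]
    sx = cumx[hi + 1] - cumx[lo]
    sy = cumy[hi + 1] - cumy[lo]
    sxx = cumxx[hi + 1] - cumxx[lo]
    sxy = cumxy[hi + 1] - cumxy[lo]

    xbar = sx / m
    ybar = sy / m
    vxx = sxx - sx * xbar
    vxy = sxy - sx * ybar
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(vxx > 0, vxy / np.where(vxx > 0, vxx, 1.0), 0.0)
    fit = ybar + slope * (x - xbar)

    with np.errstate(divide="ignore", invalid="ignore"):
        h = 1.0 / m + np.where(vxx > 0, (x - xbar) ** 2 / np.where(vxx > 0, vxx, 1.0), 0.0)
    denom = np.maximum(1.0 - h, 1e-10)
    loo = (y - fit) / denom
    return fit, loo


def _window(span: float, n: int) -> int:
    return max(2, int(round(span * n)))


def supersmooth(
    x: np.ndarray, y: np.ndarray, bass: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Variable-span smooth of y against strictly increasing x.

    Returns (smoothed, span_used).  Inputs shorter than 5 points fall back
    to a single running-line smooth whose window is chosen by leave-one-out
    absolute error; a 1-point series passes through unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise IfsgpError("x and y must be 1-D vectors of equal length")
    if np.any(np.diff(x) <= 0):
        raise IfsgpError("x must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise IfsgpError("y contains non-finite values")
    if not 0.0 <= bass <= 10.0:
        raise IfsgpError("bass must lie in [0, 10]")
    n = len(x)
    if n == 1:
        return y.copy(), np.ones(1)
    if n < 5:
        return _short_smooth(x, y)

    fits = np.empty((3, n))
    acvs = np.empty((3, n))
    mid_window = _window(SPANS[1], n)
    for k, span in enumerate(SPANS):
        fit, loo = _running_linear(x, y, _window(span, n))
        fits[k] = fit
        # smooth the absolute deleted residuals with the midrange span to
        # estimate the local cross-validated error of this span
        acvs[k], _ = _running_linear(x, np.abs(loo), mid_window)

    best = np.argmin(acvs, axis=0)
    span_vals = np.asarray(SPANS)[best]
    if bass > 0:
        resmin = acvs[best, np.arange(n)]
        woofer = acvs[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(woofer > 0, resmin / woofer, 1.0)
        span_vals = span_vals + (SPANS[2] - span_vals) * ratio ** (10.0 - bass)

    span_smooth, _ = _running_linear(x, span_vals, mid_window)
    span_smooth = np.clip(span_smooth, SPANS[0], SPANS[2])

    # interpolate between the two bracketing span smooths at each point
    result = np.empty(n)
    lower = span_smooth <= SPANS[1]
    for mask, (s_lo, s_hi), (f_lo, f_hi) in (
        (lower, (SPANS[0], SPANS[1]), (fits[0], fits[1])),
        (~lower, (SPANS[1], SPANS[2]), (fits[1], fits[2])),
    ):
        frac = (span_smooth[mask] - s_lo) / (s_hi - s_lo)
        result[mask] = (1 - frac) * f_lo[mask] + frac * f_hi[mask]

    result, _ = _running_linear(x, result, _window(SPANS[0], n))
    return result, span_smooth


def _short_smooth(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running-line smooth with window chosen by leave-one-out absolute error."""
    n = len(x)
    best_fit, best_err, best_window = None, np.inf, n
    for window in range(2, n + 1):
        fit, loo = _running_linear(x, y, window)
        err = float(np.abs(loo).sum())
        if err < best_err - 1e-12:
            best_fit, best_err, best_window = fit, err, window
    return best_fit, np.full(n, best_window / n)


def smooth_curve(
    curve: IfsCurve, smooth_x: str = "log", bass: float = 0.0
) -> SmoothedCurve:
    """Smooth an IFS accuracy curve over (log) SNP counts."""
    if smooth_x not in ("log", "linear"):
        raise IfsgpError("smooth_x must be 'log' or 'linear'")
    counts = np.asarray(curve.snp_counts, dtype=np.float64)
    x = np.log10(counts) if smooth_x == "log" else counts
    smoothed, span = supersmooth(x, np.asarray(curve.mean_r2, dtype=np.float64), bass)
    return SmoothedCurve(
        snp_counts=np.asarray(curve.snp_counts), smoothed_r2=smoothed, span_used=span
    )


def select_optimum(
    curve: IfsCurve, smooth_x: str = "log", bass: float = 0.0
) -> SelectionResult:
    """Pick the SNP count maximizing the smoothed accuracy curve.

    Ties are broken toward the smallest SNP count (parsimony);
    ``use_all_snps`` is set when the maximum sits at the final point.
    """
    smoothed = smooth_curve(curve, smooth_x=smooth_x, bass=bass)
    idx = int(np.argmax(smoothed.smoothed_r2))  # first occurrence wins ties
    optimal_count = int(smoothed.snp_counts[idx])
    return SelectionResult(
        optimal_count=optimal_count,
        optimal_smoothed_r2=float(smoothed.smoothed_r2[idx]),
        use_all_snps=optimal_count == int(smoothed.snp_counts[-1]),
        smoothed=smoothed,
    )
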