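"""Empirical mode decomposition (EMD).

Sifts a 1-D series into intrinsic mode functions (IMFs) plus a residual
trend.  Each sift subtracts the mean of the upper and lower cubic-spline
envelopes (through local maxima and minima respectively, mirror-extended at
the boundaries).  Sifting of a mode stops when the normalized squared
difference between successive sifts (the Cauchy-style SD criterion) falls
below a threshold; decomposition stops when the remainder no longer has
enough extrema to form envelopes.

Completeness holds by construction: the residual is the arithmetic
remainder of the input after all extracted IMFs, so IMFs + residual
reconstruct the input to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["ImfSet", "TrendReached", "find_extrema", "sift_once", "decompose"]


class TrendReached(Exception):
    """Raised by :func:`sift_once` when the series has too few extrema
    to form both envelopes (the remainder is a trend)."""


@dataclass
class ImfSet:
    """Ordered intrinsic mode functions plus residual trend.

    ``imfs`` has shape (n_imfs, n_samples); modes are ordered fast to slow.
    ``residual`` is the final non-IMF remainder (the nonstationary trend).
    """

    imfs: np.ndarray
    residual: np.ndarray
    n_sift_iterations: list[int]
    source_length: int

    @property
    def n_imfs(self) -> int:
        return int(self.imfs.shape[0])

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residual."""
        return self.imfs.sum(axis=0) + self.residual


def find_extrema(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local minima and maxima of a 1-D series.

    Extrema are detected by sign change of the first difference.  A flat
    plateau is reported once, at its midpoint index (rounded down).
    Endpoints are never extrema.

    Returns
    -------
    (minima, maxima)
        Integer index arrays, each sorted ascending.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 3:
        raise ValueError("need at least 3 samples to define interior extrema")

    # Compress runs of equal values so plateaus become single points.
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    if starts.size < 3:
        empty = np.array([], dtype=int)
        return empty, empty
    ends = np.concatenate((starts[1:] - 1, [x.size - 1]))
    mids = starts + (ends - starts) // 2

    d = np.sign(np.diff(x[starts]))  # entries are +-1 by construction
    interior = mids[1:-1]
    maxima = interior[(d[:-1] > 0) & (d[1:] < 0)]
    minima = interior[(d[:-1] < 0) & (d[1:] > 0)]
    return minima, maxima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Spline envelope through extrema ``idx``, mirror-extended 2 points
    at each end.  Natural cubic splines; linear fallback below 4 knots."""
    n = x.size
    k = min(2, idx.size)
    left = -idx[:k][::-1]
    right = 2 * (n - 1) - idx[-k:][::-1]
    pos = np.concatenate([left, idx, right])
    val = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
    if pos.size >= 4:
        return CubicSpline(pos, val, bc_type="natural")(np.arange(n))
    if pos.size >= 2:
        return np.interp(np.arange(n), pos, val)
    return np.full(n, val[0] if val.size else 0.0)


def _sift(x: np.ndarray, strict: bool) -> np.ndarray:
    if x.size < 3:
        raise TrendReached("series too short to sift")
    minima, maxima = find_extrema(x)
    if strict:
        enough = maxima.size >= 2 and minima.size >= 2
    else:
        # tolerate sparse extrema so decomposition can run the remainder
        # down to a true trend (< 3 extrema); envelopes then fall back to
        # linear interpolation through the mirrored points
        enough = (
            maxima.size >= 1 and minima.size >= 1 and maxima.size + minima.size >= 3
        )
    if not enough:
        raise TrendReached(
            f"too few extrema to sift ({maxima.size} maxima, {minima.size} minima)"
        )
    upper = _envelope(x, maxima)
    lower = _envelope(x, minima)
    return x - 0.5 * (upper + lower)


def sift_once(series: np.ndarray) -> np.ndarray:
    """One sifting pass: series minus the mean of its two envelopes.

    Raises
    ------
    TrendReached
        If the series has fewer than 2 maxima or 2 minima, so envelopes
        cannot be formed.
    """
    return _sift(np.asarray(series, dtype=float), strict=True)


def decompose(
    series: np.ndarray,
    max_imfs: int | None = None,
    sd_threshold: float = 0.2,
    max_siftings: int = 200,
) -> ImfSet:
    """Full EMD of a 1-D series.

    Parameters
    ----------
    series
        Input series, at least 16 samples.
    max_imfs
        Cap on the number of extracted modes; ``None`` decomposes until
        the remainder is a trend.
    sd_threshold
        Cauchy SD stopping threshold for per-mode sifting: sifting stops
        when ``sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold``.
    max_siftings
        Hard cap on sift iterations per mode.

    Returns
    -------
    ImfSet
        Extracted modes and residual.  A constant (or trend-only) input
        yields zero IMFs with ``residual == series``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size < 16:
        raise ValueError("series too short for EMD (need >= 16 samples)")
    if max_imfs is not None and max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")
    if not (sd_threshold > 0):
        raise ValueError("sd_threshold must be positive")

    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    residual = x.copy()

    while max_imfs is None or len(imfs) < max_imfs:
        h = residual
        iterations = 0
        try:
            while iterations < max_siftings:
                h_new = _sift(h, strict=False)
                iterations += 1
                denom = float(np.dot(h, h))
                sd = float(np.dot(h - h_new, h - h_new)) / denom if denom > 0 else 0.0
                h = h_new
                if sd < sd_threshold:
                    break
        except TrendReached:
            if iterations == 0:
                break  # residual is already the trend
        imfs.append(h)
        sift_counts.append(iterations)
        residual = residual - h

    imf_arr = (
        np.vstack(imfs) if imfs else np.empty((0, x.size), dtype=float)
    )
    return ImfSet(
        imfs=imf_arr,
        residual=residual,
        n_sift_iterations=sift_counts,
        source_length=x.size,
    )
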