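"""Conventional detrended fluctuation analysis (DFA).

Textbook box-wise polynomial detrending: integrate the mean-removed
series, partition the profile into non-overlapping windows of size n (both
from the start and from the end, so all data are used), subtract a
least-squares polynomial per window, and pool the residual RMS into F(n).
The scaling exponent alpha is the log-log slope of F(n) vs n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DfaCurve", "default_windows", "dfa"]


@dataclass
class DfaCurve:
    """Detrended fluctuation function on a grid of window sizes."""

    window_sizes: np.ndarray
    F: np.ndarray
    detrend_order: int


def default_windows(n_samples: int, n_windows: int = 20) -> np.ndarray:
    """Log-spaced integer window sizes in [4, n_samples/4]."""
    lo, hi = 4, n_samples // 4
    if hi < lo:
        raise ValueError("series too short for DFA (need >= 16 samples)")
    w = np.unique(
        np.round(np.logspace(np.log10(lo), np.log10(hi), n_windows)).astype(int)
    )
    return w[(w >= lo) & (w <= hi)]


def _window_ss(profile: np.ndarray, n: int, order: int) -> tuple[float, int]:
    """Sum of squared detrending residuals over forward+reverse windows
    of size n; returns (sum of squares, number of residual samples)."""
    N = profile.size
    k = N // n
    t = np.arange(n, dtype=float)
    V = np.vander(t, order + 1)
    total = 0.0
    count = 0
    for seg in (profile[: k * n], profile[N - k * n :]):
        Y = seg.reshape(k, n).T  # (n, k): one column per window
        beta, *_ = np.linalg.lstsq(V, Y, rcond=None)
        resid = Y - V @ beta
        total += float(np.sum(resid * resid))
        count += resid.size
    return total, count


def dfa(
    series: np.ndarray,
    window_sizes: np.ndarray | None = None,
    detrend_order: int = 1,
) -> tuple[DfaCurve, float]:
    """Conventional DFA of a 1-D series.

    Parameters
    ----------
    series
        Input series (a noise-like signal; it is integrated internally).
    window_sizes
        Window sizes in samples; default 20 log-spaced sizes in
        [4, N/4].  Sizes outside [max(4, order+2), N/4] are rejected.
    detrend_order
        Per-window detrending polynomial order (1 = DFA-1).

    Returns
    -------
    (DfaCurve, alpha)
        Fluctuation curve and the OLS log-log slope over all windows.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    N = x.size
    if window_sizes is None:
        window_sizes = default_windows(N)
    ws = np.unique(np.asarray(window_sizes, dtype=int))
    lo = max(4, detrend_order + 2)
    ws = ws[(ws >= lo) & (ws <= N // 4)]
    if ws.size < 2:
        raise ValueError("need at least 2 admissible window sizes")

    profile = np.cumsum(x - x.mean())
    F = np.empty(ws.size)
    for i, n in enumerate(ws):
        ss, cnt = _window_ss(profile, int(n), detrend_order)
        F[i] = np.sqrt(ss / cnt)

    good = F > 0
    alpha = float(np.polyfit(np.log10(ws[good]), np.log10(F[good]), 1)[0])
    return DfaCurve(window_sizes=ws, F=F, detrend_order=detrend_order), alpha
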