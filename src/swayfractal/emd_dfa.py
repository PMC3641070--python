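"""EMD-embedded detrended fluctuation analysis (EMD-DFA).

The pipeline: build the cumulative profile of a (magnitude) series,
decompose it by EMD, read the *intrinsic scales* off each IMF as the
inter-minima distances, then for every intrinsic scale s reconstruct a
per-scale series by keeping only the IMF segments whose inter-minima
length equals s (zeros elsewhere) and summing across IMFs.  The RMS of
that per-scale series is the fluctuation F(s); a power law F(s) ~ s^alpha
with two linear regimes in log-log space yields a short- and a long-term
scaling exponent separated by a least-squares-selected crossover scale.

Because the scales are derived from the signal's own oscillations rather
than from a fixed window grid, trends are isolated in the EMD residual
(which is excluded) instead of being fit per window as in conventional DFA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cop_signal import MagnitudeSeries, cumulative_profile
from .emd import ImfSet, decompose, find_extrema

__all__ = [
    "IntrinsicScaleTable",
    "FluctuationCurve",
    "ScalingResult",
    "EmdDfaConfig",
    "NoIntrinsicScalesError",
    "intrinsic_scales",
    "reconstruct_at_scale",
    "fluctuation_function",
    "fit_crossover",
    "emd_dfa",
]

logger = logging.getLogger(__name__)


class NoIntrinsicScalesError(ValueError):
    """No IMF contains at least two local minima."""


@dataclass
class IntrinsicScaleTable:
    """Intrinsic time scales extracted from an IMF set.

    ``per_imf_distances[k]`` holds the inter-minima distances (integer
    samples) of IMF k; ``per_imf_minima[k]`` the minima indices they were
    measured between.  ``scales`` is the sorted union of all distances and
    ``segment_counts[s]`` the number of segments of length s pooled over
    IMFs.  The EMD residual contributes nothing (it is the removed trend).
    """

    per_imf_distances: list[np.ndarray]
    per_imf_minima: list[np.ndarray]
    scales: np.ndarray
    segment_counts: dict[int, int]
    source_length: int


@dataclass
class FluctuationCurve:
    """(scale, F(scale)) pairs on which the power law is fit.

    ``scales`` are in samples (float to allow binned representative
    scales); ``retained_counts`` is the number of samples contributing to
    each F value.
    """

    scales: np.ndarray
    F: np.ndarray
    retained_counts: np.ndarray
    normalization_mode: str
    sample_rate: float | None = None

    @property
    def scales_ms(self) -> np.ndarray | None:
        if self.sample_rate is None:
            return None
        return self.scales / self.sample_rate * 1000.0


@dataclass
class ScalingResult:
    """Two-regime power-law fit of a fluctuation curve."""

    alpha_short: float
    alpha_long: float
    alpha_global: float
    crossover_scale: float  # samples; nan when single-slope fallback
    crossover_ms: float = float("nan")
    sse_total: float = float("nan")
    r2_short: float = float("nan")
    r2_long: float = float("nan")
    n_points_short: int = 0
    n_points_long: int = 0
    single_slope: bool = False
    no_distinct_regimes: bool = False


@dataclass
class EmdDfaConfig:
    """Tunable parameters of the EMD-DFA pipeline.

    normalization
        "retained" (default): F(s) is the RMS over the samples actually
        retained at scale s, so F estimates the oscillation amplitude at
        that scale regardless of how many segments carry it.  "full":
        divide the summed squares by the full record length N instead
        (zero-substituted samples included), which couples F(s) to the
        scale occupancy.
    binning
        "log" (default): pool scales into log-spaced bins
        (``bins_per_decade`` per decade) so every curve point aggregates
        many segments; "merge": pool adjacent scales only until each bin
        retains ``min_bin_count`` samples; "none": every distinct integer
        scale is its own curve point.
    min_scale, max_scale_frac
        Analyzed scale range: [min_scale, N * max_scale_frac] samples.
        Sub-4-sample segments cannot represent an oscillation, and scales
        beyond N/8 rest on a handful of segments.
    min_points_per_segment
        Fewest curve points a fitted regime may span.  With the default
        binning this forces each regime to cover about a decade of
        scales, which suppresses spurious crossovers on monofractal
        signals; lower it (with finer binning) to resolve crossovers
        below ~30 samples.
    """

    sd_threshold: float = 0.2
    max_imfs: int | None = None
    max_siftings: int = 200
    normalization: str = "retained"
    min_points_per_segment: int = 5
    binning: str = "log"
    bins_per_decade: int = 5
    min_bin_count: int = 100
    min_scale: int = 4
    max_scale_frac: float = 0.125

    def __post_init__(self) -> None:
        if self.normalization not in ("full", "retained"):
            raise ValueError("normalization must be 'full' or 'retained'")
        if self.binning not in ("none", "merge", "log"):
            raise ValueError("binning must be 'none', 'merge' or 'log'")
        if self.min_points_per_segment < 2:
            raise ValueError("min_points_per_segment must be >= 2")
        if self.min_scale < 2:
            raise ValueError("min_scale must be >= 2")
        if not (0 < self.max_scale_frac <= 1):
            raise ValueError("max_scale_frac must lie in (0, 1]")


def intrinsic_scales(imfset: ImfSet) -> IntrinsicScaleTable:
    """Inter-minima distances of every IMF; the residual is excluded.

    Raises
    ------
    NoIntrinsicScalesError
        If no IMF has at least 2 local minima.
    """
    per_dist: list[np.ndarray] = []
    per_min: list[np.ndarray] = []
    counts: dict[int, int] = {}
    for k in range(imfset.n_imfs):
        imf = imfset.imfs[k]
        if imf.size >= 3:
            minima, _ = find_extrema(imf)
        else:
            minima = np.array([], dtype=int)
        dists = np.diff(minima) if minima.size >= 2 else np.array([], dtype=int)
        per_min.append(minima)
        per_dist.append(dists.astype(int))
        for s, c in zip(*np.unique(dists, return_counts=True)):
            counts[int(s)] = counts.get(int(s), 0) + int(c)
    if not counts:
        raise NoIntrinsicScalesError(
            "no IMF has two local minima; no intrinsic scales exist"
        )
    return IntrinsicScaleTable(
        per_imf_distances=per_dist,
        per_imf_minima=per_min,
        scales=np.array(sorted(counts), dtype=int),
        segment_counts=counts,
        source_length=imfset.source_length,
    )


def _masked_sum(
    imfset: ImfSet, table: IntrinsicScaleTable, lengths: set[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of IMFs keeping only inter-minima segments whose length is in
    ``lengths``; returns (series, union retained mask).

    A segment spans the half-open index range [m_k, m_{k+1}) so segments
    within one IMF partition the span between its first and last minima.
    """
    n = imfset.source_length
    y = np.zeros(n)
    union = np.zeros(n, dtype=bool)
    for k in range(imfset.n_imfs):
        minima = table.per_imf_minima[k]
        if minima.size < 2:
            continue
        mask = np.zeros(n, dtype=bool)
        dists = np.diff(minima)
        for j in np.flatnonzero(np.isin(dists, list(lengths))):
            mask[minima[j] : minima[j + 1]] = True
        y[mask] += imfset.imfs[k][mask]
        union |= mask
    return y, union


def reconstruct_at_scale(
    imfset: ImfSet, table: IntrinsicScaleTable, s: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-scale series Y_s: IMF samples in segments of length s are kept,
    all other samples replaced by zeros, then summed across IMFs.

    Returns
    -------
    (Y_s, mask)
        The reconstructed series and the boolean retained-sample mask
        (union over IMFs).

    Raises
    ------
    ValueError
        If ``s`` is not in the table's scale set.
    """
    s = int(s)
    if s not in table.segment_counts:
        raise ValueError(f"scale {s} is not an intrinsic scale of this IMF set")
    return _masked_sum(imfset, table, {s})


def fluctuation_function(
    y_s: np.ndarray, mask: np.ndarray, normalization_mode: str = "full"
) -> float:
    """Root-mean-square fluctuation of a per-scale series.

    Mode "full": sqrt(sum(Y_s^2)/N) over all N samples, zeros included.
    Mode "retained": divide by the retained-sample count instead.

    Raises
    ------
    ValueError
        If the mask retains no samples (F undefined at this scale).
    """
    y_s = np.asarray(y_s, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n_ret = int(mask.sum())
    if n_ret == 0:
        raise ValueError("no retained samples: fluctuation undefined")
    ss = float(np.dot(y_s, y_s))
    if normalization_mode == "full":
        return float(np.sqrt(ss / y_s.size))
    if normalization_mode == "retained":
        return float(np.sqrt(ss / n_ret))
    raise ValueError("normalization_mode must be 'full' or 'retained'")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS fit y = a*x + b; returns (a, b, sse, r2)."""
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    sse = float(np.dot(resid, resid))
    sst = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return float(a), float(b), sse, r2


def fit_crossover(
    scales: np.ndarray,
    F: np.ndarray,
    min_points_per_segment: int = 3,
    slope_diff_threshold: float = 0.05,
) -> ScalingResult:
    """Two-regime power-law fit in (log10 s, log10 F) space.

    Every admissible breakpoint between the sorted scales is scanned; two
    independent OLS lines are fit left/right of it and the breakpoint with
    the smallest total SSE wins (ties to the smaller index).  The left
    slope is alpha_short, the right slope alpha_long; the crossover scale
    is the geometric mean of the two scales adjacent to the breakpoint.

    With fewer than ``2 * min_points_per_segment`` usable points the
    result falls back to a single global slope (``single_slope`` flag);
    a slope difference below ``slope_diff_threshold`` sets the
    ``no_distinct_regimes`` flag.
    """
    s = np.asarray(scales, dtype=float)
    f = np.asarray(F, dtype=float)
    keep = np.isfinite(s) & np.isfinite(f) & (s > 0) & (f > 0)
    s, f = s[keep], f[keep]
    order = np.argsort(s)
    ls, lf = np.log10(s[order]), np.log10(f[order])
    m = ls.size
    if m < 2:
        raise ValueError("need at least 2 positive finite points to fit")

    a_g, _, sse_g, r2_g = _ols_line(ls, lf)

    if m < 2 * min_points_per_segment:
        return ScalingResult(
            alpha_short=a_g,
            alpha_long=a_g,
            alpha_global=a_g,
            crossover_scale=float("nan"),
            sse_total=sse_g,
            r2_short=r2_g,
            r2_long=r2_g,
            n_points_short=m,
            n_points_long=m,
            single_slope=True,
            no_distinct_regimes=True,
        )

    best: tuple[float, int] | None = None
    fits: dict[int, tuple] = {}
    for b in range(min_points_per_segment, m - min_points_per_segment + 1):
        a_l, _, sse_l, r2_l = _ols_line(ls[:b], lf[:b])
        a_r, _, sse_r, r2_r = _ols_line(ls[b:], lf[b:])
        sse = sse_l + sse_r
        if best is None or sse < best[0]:
            best = (sse, b)
            fits[b] = (a_l, a_r, r2_l, r2_r, sse)
    sse_total, b = best
    a_l, a_r, r2_l, r2_r, _ = fits[b]
    crossover = float(np.sqrt(10 ** ls[b - 1] * 10 ** ls[b]))
    return ScalingResult(
        alpha_short=a_l,
        alpha_long=a_r,
        alpha_global=a_g,
        crossover_scale=crossover,
        sse_total=sse_total,
        r2_short=r2_l,
        r2_long=r2_r,
        n_points_short=int(b),
        n_points_long=int(m - b),
        single_slope=False,
        no_distinct_regimes=abs(a_l - a_r) < slope_diff_threshold,
    )


def _merge_bins(scales: list[int], table: IntrinsicScaleTable, min_count: int) -> list[list[int]]:
    """Group sorted scales into adjacent bins whose pooled retained-sample
    count (segments * scale) reaches ``min_count``."""
    bins: list[list[int]] = []
    current: list[int] = []
    acc = 0
    for s in scales:
        current.append(int(s))
        acc += table.segment_counts[int(s)] * int(s)
        if acc >= min_count:
            bins.append(current)
            current, acc = [], 0
    if current:
        if bins:
            bins[-1].extend(current)  # fold the short tail into the last bin
        else:
            bins.append(current)
    return bins


def _log_bins(scales: list[int], bins_per_decade: int) -> list[list[int]]:
    """Group sorted scales into log-spaced bins of fixed decade fraction."""
    lo, hi = np.log10(scales[0]), np.log10(scales[-1])
    n_bins = max(6, int(np.ceil((hi - lo) * bins_per_decade)))
    edges = np.logspace(lo, hi, n_bins + 1)
    edges[-1] *= 1 + 1e-9
    groups = []
    for b in range(n_bins):
        grp = [s for s in scales if edges[b] <= s < edges[b + 1]]
        if grp:
            groups.append(grp)
    return groups


def emd_dfa(
    series: MagnitudeSeries | np.ndarray,
    config: EmdDfaConfig | None = None,
    sample_rate: float | None = None,
) -> tuple[FluctuationCurve, ScalingResult]:
    """Full EMD-DFA pipeline on a magnitude (or generic 1-D) series.

    Chains: cumulative profile -> EMD -> intrinsic scales -> per-scale
    reconstruction + fluctuation function -> two-regime crossover fit.
    Deterministic for fixed input and config.

    Parameters
    ----------
    series
        :class:`MagnitudeSeries` (carries its sample rate) or a plain
        array with ``sample_rate`` given separately; at least 512 samples.
    config
        :class:`EmdDfaConfig`; defaults used when omitted.

    Returns
    -------
    (FluctuationCurve, ScalingResult)
        The crossover scale is reported both in samples and, when a
        sample rate is known, in milliseconds.
    """
    cfg = config or EmdDfaConfig()
    if isinstance(series, MagnitudeSeries):
        values = series.values
        fs = series.sample_rate
    else:
        values = np.asarray(series, dtype=float)
        fs = sample_rate
    if values.size < 512:
        raise ValueError(
            f"series has {values.size} samples; EMD-DFA needs at least 512"
        )

    profile = cumulative_profile(values)
    imfset = decompose(
        profile.values,
        max_imfs=cfg.max_imfs,
        sd_threshold=cfg.sd_threshold,
        max_siftings=cfg.max_siftings,
    )
    table = intrinsic_scales(imfset)

    s_max = values.size * cfg.max_scale_frac
    usable = [int(s) for s in table.scales if cfg.min_scale <= s <= s_max]
    if not usable:
        usable = [int(s) for s in table.scales]  # degenerate scale set
        logger.warning("no intrinsic scales inside [%d, %.0f]; using all", cfg.min_scale, s_max)
    if cfg.binning == "log":
        groups = _log_bins(usable, cfg.bins_per_decade)
    elif cfg.binning == "merge":
        groups = _merge_bins(usable, table, cfg.min_bin_count)
    else:
        groups = [[s] for s in usable]

    out_scales: list[float] = []
    out_F: list[float] = []
    out_counts: list[int] = []
    for group in groups:
        y_s, mask = _masked_sum(imfset, table, set(group))
        n_ret = int(mask.sum())
        if n_ret == 0:
            logger.warning("scale group %s retained no samples; dropped", group)
            continue
        f_val = fluctuation_function(y_s, mask, cfg.normalization)
        if not (f_val > 0):
            logger.warning("scale group %s has zero fluctuation; dropped", group)
            continue
        # count-weighted geometric-mean representative scale for a bin
        w = np.array(
            [table.segment_counts[s] * s for s in group], dtype=float
        )
        rep = float(np.exp(np.average(np.log(group), weights=w)))
        out_scales.append(rep)
        out_F.append(f_val)
        out_counts.append(n_ret)

    curve = FluctuationCurve(
        scales=np.array(out_scales),
        F=np.array(out_F),
        retained_counts=np.array(out_counts, dtype=int),
        normalization_mode=cfg.normalization,
        sample_rate=fs,
    )
    if curve.scales.size < 6:
        logger.warning(
            "only %d usable scales; falling back to a single global slope",
            curve.scales.size,
        )
    result = fit_crossover(
        curve.scales, curve.F, min_points_per_segment=cfg.min_points_per_segment
    )
    if fs is not None and np.isfinite(result.crossover_scale):
        result.crossover_ms = result.crossover_scale / fs * 1000.0
    return curve, result
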