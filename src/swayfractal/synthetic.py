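"""Seeded synthetic generators for validating fractal sway analysis.

No public COP recordings accompany the method, so validation rests on
processes with known scaling theory:

* fractional Gaussian noise (fGn) with Hurst index H, for which the DFA
  exponent is alpha = H (and alpha = H + 1 for its running sum, fBm);
* two-regime composites whose log-log fluctuation slope changes from
  alpha_fast (short scales / high frequencies) to alpha_slow (long
  scales) at a chosen crossover scale;
* COP-like 2-D trajectories: integrals of composite noises in mm units at
  force-plate sampling rates, with optional slow postural drift.

A periodogram-based spectral exponent beta provides the classical
cross-check beta = 2*alpha - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal as sps

from .cop_signal import CopTrajectory

__all__ = [
    "SyntheticSpec",
    "SpectralResult",
    "fgn_autocovariance",
    "generate_fgn",
    "generate_fbm",
    "generate_composite",
    "generate_cop2d",
    "spectral_exponent",
]

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic COP-like trial.

    Defaults emulate the target recording protocol: 20 s of quiet stance
    at 1000 Hz, displacement increments with pink-noise-like short-scale
    scaling (alpha_fast = 1.0) crossing over to white-noise-like
    long-scale scaling (alpha_slow = 0.5), radial RMS displacement of a
    few mm, plus one slow mm-scale drift cycle per trial.
    """

    kind: str = "cop2d"
    n: int = 20000
    sample_rate: float = 1000.0
    hurst: float = 0.5
    alpha_fast: float = 1.0
    alpha_slow: float = 0.5
    crossover_scale: int = 64
    rms_mm: float = 3.0
    drift_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 512:
            raise ValueError("n must be >= 512")
        if self.kind in ("fgn", "fbm") and not (0 < self.hurst < 1):
            raise ValueError("hurst must lie in (0, 1)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class SpectralResult:
    """Spectral exponent beta = -(log-log periodogram slope)."""

    beta: float
    f_low: float
    f_high: float
    n_bins: int


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fGn:
    gamma(k) = 0.5(|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H))."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_fgn(
    hurst: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    Embeds the fGn autocovariance in a circulant matrix of size 2n whose
    eigenvalues come from one FFT; a complex-Gaussian synthesis then has
    exactly the target covariance (unit variance).  If the embedding is
    not positive semi-definite (extreme H at small n) the generator falls
    back to random-phase spectral synthesis with a logged warning.
    Deterministic per seed.
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must lie in (0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)

    m = 2 * n
    gamma = fgn_autocovariance(hurst, np.arange(n + 1))
    c = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n, circulant row
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        logger.warning(
            "circulant embedding not PSD for H=%.3f, n=%d; "
            "falling back to spectral synthesis",
            hurst,
            n,
        )
        return _spectral_fgn(hurst, n, rng)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.sqrt(m) * np.fft.ifft(np.sqrt(lam) * z).real
    return x[:n]


def _spectral_fgn(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn: random-phase synthesis with PSD ~ f^-(2H-1)."""
    beta = 2.0 * hurst - 1.0
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_fbm(
    hurst: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Fractional Brownian motion: running sum of fGn (DFA alpha = H + 1)."""
    return np.cumsum(generate_fgn(hurst, n, seed))


def generate_composite(
    alpha_fast: float,
    alpha_slow: float,
    crossover_scale: int,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Noise with a scaling crossover: DFA slope ~ alpha_fast at scales
    below ``crossover_scale`` and ~ alpha_slow above it.

    Built in the Fourier domain: random phases with power-law amplitude
    f^(-beta/2) where beta = 2*alpha - 1, using alpha_fast above the
    splice frequency 1/crossover_scale and alpha_slow below it, with the
    two branches amplitude-matched at the splice so the spectrum has no
    step.  Unit sample variance; deterministic per seed.
    """
    if not (8 <= crossover_scale <= n / 8):
        raise ValueError(
            f"crossover_scale must lie in [8, n/8]; got {crossover_scale} for n={n}"
        )
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n)
    f_c = 1.0 / crossover_scale
    beta_fast = 2.0 * alpha_fast - 1.0
    beta_slow = 2.0 * alpha_slow - 1.0

    amp = np.zeros_like(freqs)
    nz = freqs > 0
    f = freqs[nz]
    high = f > f_c
    a = np.empty_like(f)
    a[~high] = f[~high] ** (-beta_slow / 2.0)
    # continuity at f_c: match the two power laws there
    match = f_c ** ((beta_fast - beta_slow) / 2.0)
    a[high] = match * f[high] ** (-beta_fast / 2.0)
    amp[nz] = a

    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_cop2d(spec: SyntheticSpec | None = None, **kwargs: Any) -> CopTrajectory:
    """COP-like 2-D trajectory at force-plate rates.

    x and y are independent scaled integrals of composite noises (so the
    displacement increments carry the spec's fast/slow exponents), plus an
    optional slow sinusoidal drift (one cycle per trial, quadrature phase
    between axes).  Each axis is scaled so the radial RMS displacement
    about the mean equals ``spec.rms_mm``.  Metadata records the
    generating parameters as ground truth.
    """
    if spec is None:
        spec = SyntheticSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SyntheticSpec or keyword fields, not both")
    ss = np.random.SeedSequence(spec.seed)
    rng_x, rng_y = [np.random.default_rng(s) for s in ss.spawn(2)]

    coords = []
    for rng in (rng_x, rng_y):
        incr = generate_composite(
            spec.alpha_fast, spec.alpha_slow, spec.crossover_scale, spec.n - 1, rng
        )
        path = np.concatenate([[0.0], np.cumsum(incr)])
        path -= path.mean()
        sd = path.std()
        target = spec.rms_mm / np.sqrt(2.0)  # split radial RMS across axes
        coords.append(path * (target / sd) if sd > 0 else path)

    t = np.arange(spec.n) / spec.sample_rate
    period = spec.n / spec.sample_rate
    x = coords[0] + spec.drift_mm * np.sin(2 * np.pi * t / period)
    y = coords[1] + spec.drift_mm * np.cos(2 * np.pi * t / period)

    meta = {
        "generator": "cop2d",
        "seed": spec.seed,
        "alpha_fast": spec.alpha_fast,
        "alpha_slow": spec.alpha_slow,
        "crossover_scale": spec.crossover_scale,
        "rms_mm": spec.rms_mm,
        "drift_mm": spec.drift_mm,
    }
    return CopTrajectory(x=x, y=y, sample_rate=spec.sample_rate, meta=meta)


def spectral_exponent(
    series: np.ndarray,
    n_bins: int = 30,
    exclude_edge_bins: int = 3,
) -> SpectralResult:
    """Spectral exponent beta from the periodogram.

    Hann-windowed, mean-removed periodogram; the 3 lowest and 3 highest
    positive-frequency bins are excluded, the remainder is averaged in
    log-spaced frequency bands, and beta is the negated OLS slope of
    log10 power vs log10 frequency over those bands.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 256:
        raise ValueError("series must have at least 256 samples")
    freqs, power = sps.periodogram(x, window="hann", detrend="constant")
    pos = (freqs > 0) & (power > 0)
    freqs, power = freqs[pos], power[pos]
    k = exclude_edge_bins
    freqs, power = freqs[k : freqs.size - k], power[k : power.size - k]

    edges = np.logspace(np.log10(freqs[0]), np.log10(freqs[-1]), n_bins + 1)
    edges[-1] *= 1 + 1e-12
    idx = np.digitize(freqs, edges) - 1
    lf, lp = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            lf.append(np.log10(freqs[sel]).mean())
            lp.append(np.log10(power[sel]).mean())
    lf, lp = np.array(lf), np.array(lp)
    slope = float(np.polyfit(lf, lp, 1)[0])
    return SpectralResult(
        beta=-slope,
        f_low=float(freqs[0]),
        f_high=float(freqs[-1]),
        n_bins=int(lf.size),
    )
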