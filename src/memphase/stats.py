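"""Autocorrelation-corrected bootstrap statistics for trajectory time series.

Frames saved every few tens of nanoseconds are strongly time-correlated, so a
naive bootstrap of per-frame observations underestimates uncertainty.  The
correction used throughout this package resamples fewer points: for a series
of n frames with integrated autocorrelation time tau, each bootstrap resample
draws n_eff = max(1, round(n / tau)) points with replacement.  For 666 frames
(20 μs at 30 ns/frame) and tau = 2 that is 333 points per resample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeriesStats",
    "autocorrelation",
    "integrated_act",
    "effective_sample_size",
    "corrected_bootstrap",
    "frames_in_window",
]


@dataclass(frozen=True)
class SeriesStats:
    """Mean with a 95% (by default) corrected-bootstrap CI."""

    n: int
    tau: float
    n_eff: int
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    level: float = 0.95
    degenerate: bool = False  # constant input series


def frames_in_window(duration_ns: float, frame_interval_ns: float) -> int:
    """Number of whole frames in an analysis window (floor of the ratio).

    20 000 ns at 30 ns/frame -> 666 frames.
    """
    if frame_interval_ns <= 0:
        raise ValueError("frame interval must be positive")
    return int(duration_ns // frame_interval_ns)


def autocorrelation(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Empirical normalized autocorrelation rho(0..max_lag), FFT-based."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag is None:
        max_lag = n - 1
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series has no autocorrelation")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1].real
    return acov / var


def integrated_act(series: np.ndarray) -> tuple[float, bool]:
    """Integrated autocorrelation time with initial-positive-sequence cutoff.

    tau = 1 + 2 sum_{k=1}^{K} rho(k) where K is the last lag before the
    empirical autocorrelation first drops to <= 0; clamped to [1, n].  Returns
    (tau, degenerate); a constant series is degenerate with tau = 1.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("series too short for an IACT estimate (need >= 8)")
    if np.all(x == x[0]):
        return 1.0, True
    rho = autocorrelation(x)
    nonpos = np.flatnonzero(rho[1:] <= 0)
    k_stop = nonpos[0] if len(nonpos) else n - 1
    tau = 1.0 + 2.0 * rho[1: 1 + k_stop].sum()
    return float(np.clip(tau, 1.0, n)), False


def effective_sample_size(n: int, tau: float) -> int:
    """Resample size: n reduced proportionally to tau (666, tau 2 -> 333)."""
    return max(1, int(round(n / tau)))


def corrected_bootstrap(series: np.ndarray, n_boot: int = 1000,
                        level: float = 0.95, seed: int = 0,
                        tau: float | None = None) -> SeriesStats:
    """Percentile bootstrap CI on the mean with IACT-reduced resample size.

    Each of ``n_boot`` resamples draws n_eff = max(1, round(n / tau)) points
    with replacement; the CI is the (alpha/2, 1 - alpha/2) percentile span of
    the resampled means.  Fully deterministic for a fixed seed.  ``tau`` may
    be supplied to bypass estimation (e.g. from a longer reference series).
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("series too short to bootstrap (need >= 8)")
    if tau is None:
        tau, degenerate = integrated_act(x)
    else:
        degenerate = False
        tau = float(np.clip(tau, 1.0, n))
    n_eff = effective_sample_size(n, tau)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n_eff))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return SeriesStats(n=n, tau=tau, n_eff=n_eff, mean=float(x.mean()),
                       ci_low=float(lo), ci_high=float(hi), n_boot=n_boot,
                       seed=seed, level=level, degenerate=degenerate)
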