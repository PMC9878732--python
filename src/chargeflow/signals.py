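"""Time- and frequency-domain correlation analysis of charge-flow series.

Two estimators, used for two different purposes:

* :func:`cross_correlation` returns the *per-lag normalized* estimate

      R_xy(tau_k) = sum_over_overlap x~(t) y~(t+tau) /
                    sqrt(sum x~^2 * sum y~^2)        (sums over the overlap)

  of the globally mean-subtracted series x~, y~. The Cauchy-Schwarz
  inequality bounds it to [-1, 1] at every lag, which is what the
  cross-correlation *maps* report. Lags are capped at half the record
  length to bound the estimator variance.

* :func:`cross_power_spectrum` transforms the *biased* (fixed-denominator)
  cross-correlation, whose autospectrum is non-negative by construction
  (it is |X(nu)|^2 up to normalization). Shared oscillation frequencies of
  the two series appear as peaks of |S_xy(nu)|.

Frequencies are reported in cm^-1; the attainable resolution is set by the
record length, nu_res = 1/(c * T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .constants import SPEED_OF_LIGHT_CM_PER_FS
from .observables import TimeSeriesSet

__all__ = [
    "CorrelationFunction",
    "CrossCorrelationMap",
    "SpectralDensity",
    "cross_correlation",
    "correlation_map",
    "cross_power_spectrum",
    "spectral_resolution",
    "dominant_frequencies",
]


@dataclass
class CorrelationFunction:
    """Normalized lagged cross-correlation R_xy(tau) on a symmetric lag grid."""

    lags_fs: np.ndarray
    values: np.ndarray
    dt_fs: float

    def __post_init__(self) -> None:
        self.lags_fs = np.asarray(self.lags_fs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_fs.shape != self.values.shape:
            raise ValueError("lag and value arrays must have the same shape")

    def at_zero_lag(self) -> float:
        return float(self.values[self.lags_fs.size // 2])

    def extremum(self) -> tuple[float, float]:
        """(signed R, lag in fs) at the lag maximizing |R|.

        Ties are broken toward the smallest |lag|, then toward negative lag.
        """
        a = np.abs(self.values)
        best = np.max(a)
        cand = np.flatnonzero(a >= best - 1e-15)
        # sort candidates by (|lag|, lag): smallest magnitude first, negative before positive
        order = sorted(cand, key=lambda i: (round(abs(self.lags_fs[i]) / self.dt_fs), self.lags_fs[i]))
        i = order[0]
        return float(self.values[i]), float(self.lags_fs[i])


@dataclass
class CrossCorrelationMap:
    """Extremal signed correlations for every unique series pair.

    ``entries[(x, y)] = (R, lag_fs)`` with pairs stored once in the order of
    ``labels`` (upper triangle; the diagonal autocorrelation is identically
    1 at zero lag and is omitted).
    """

    labels: list
    entries: dict
    zero_lag_entries: dict = field(default_factory=dict)

    def value(self, a: str, b: str) -> tuple[float, float]:
        if (a, b) in self.entries:
            return self.entries[(a, b)]
        r, lag = self.entries[(b, a)]
        return r, -lag

    def to_matrix(self, zero_lag: bool = False) -> np.ndarray:
        """Symmetric matrix of R values (diagonal = 1), for rendering."""
        k = len(self.labels)
        m = np.eye(k)
        src = self.zero_lag_entries if zero_lag else self.entries
        for (a, b), (r, _) in src.items():
            i, j = self.labels.index(a), self.labels.index(b)
            m[i, j] = m[j, i] = r
        return m

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "x": a,
                "y": b,
                "R_extremal": r,
                "lag_fs": lag,
                "R_zero_lag": self.zero_lag_entries.get((a, b), (np.nan,))[0],
            }
            for (a, b), (r, lag) in self.entries.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, ax=None, zero_lag: bool = False):
        """Upper-triangle heatmap on a red-blue diverging scale in [-1, 1]."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3.5))
        m = self.to_matrix(zero_lag=zero_lag)
        masked = np.where(np.triu(np.ones_like(m, dtype=bool)), m, np.nan)
        im = ax.imshow(masked, cmap="RdBu", vmin=-1.0, vmax=1.0)
        ax.set_xticks(range(len(self.labels)), self.labels, rotation=45, ha="right")
        ax.set_yticks(range(len(self.labels)), self.labels)
        ax.figure.colorbar(im, ax=ax, label="R")
        return ax


@dataclass
class SpectralDensity:
    """One-sided cross power spectrum S_xy(nu) on a uniform cm^-1 grid."""

    frequencies_cm1: np.ndarray
    values: np.ndarray            # complex
    resolution_cm1: float
    _full_values: np.ndarray | None = None
    _full_freqs: np.ndarray | None = None
    _lag_count: int | None = None
    _dt_fs: float | None = None

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def to_correlation(self) -> CorrelationFunction:
        """Invert the transform, recovering the biased correlation estimate."""
        if self._full_values is None:
            raise ValueError("full spectrum not retained; cannot invert")
        L = (self._lag_count - 1) // 2
        r = np.fft.ifft(self._full_values)[: self._lag_count].real
        lags = np.arange(-L, L + 1) * self._dt_fs
        return CorrelationFunction(lags, r, self._dt_fs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency_cm1": self.frequencies_cm1, "magnitude": self.magnitude(),
             "phase_rad": self.phase()}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------


def _prepare(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"series lengths differ: {x.size} vs {y.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    if np.max(np.abs(xc)) == 0.0 or np.max(np.abs(yc)) == 0.0:
        raise ValueError("constant (zero-variance) series carry no correlation information")
    return xc, yc


def _lag_window(n: int, dt_fs: float, max_lag_fs) -> int:
    L = n // 2 if max_lag_fs is None else int(round(max_lag_fs / dt_fs))
    return max(0, min(L, n - 1))


def cross_correlation(x, y, dt_fs: float, max_lag_fs: float | None = None) -> CorrelationFunction:
    """Normalized cross-correlation R_xy(tau) = <x(t) y(t+tau)> / norm.

    Both series are mean-subtracted over the full record; at each lag the
    products and the normalization sums run over the overlapping window, so
    |R| <= 1 holds exactly. Lags cover [-max_lag, +max_lag] (default half
    the record). The lagged products are evaluated with an FFT-based
    correlation; the result is identical to the direct double loop.
    """
    from scipy.signal import correlate

    xc, yc = _prepare(x, y)
    n = xc.size
    L = _lag_window(n, dt_fs, max_lag_fs)

    # numerator: N(k) = sum_t x~(t) y~(t+k), k = -L..L
    full = correlate(yc, xc, mode="full", method="fft")
    num = full[n - 1 - L: n + L]

    # overlap-window energy sums via cumulative sums
    cx = np.concatenate([[0.0], np.cumsum(xc * xc)])
    cy = np.concatenate([[0.0], np.cumsum(yc * yc)])
    ks = np.arange(-L, L + 1)
    kp = np.maximum(ks, 0)
    km = np.maximum(-ks, 0)
    dx = cx[n - kp] - cx[km]
    dy = cy[n - km] - cy[kp]
    denom = np.sqrt(dx * dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    # clamp round-off excursions just past +-1
    r = np.clip(r, -1.0, 1.0)
    return CorrelationFunction(ks * dt_fs, r, dt_fs)


def correlation_map(
    series_set: TimeSeriesSet, max_lag_fs: float | None = None
) -> CrossCorrelationMap:
    """Cross-correlation map over every unique pair of series.

    For each pair the signed R at the lag maximizing |R| is stored together
    with that lag (ties toward the smallest |lag|, then toward negative
    lag); the zero-lag slice is kept alongside since in-phase/antiphase
    patterns are often read off at tau = 0.
    """
    if len(series_set.names) < 2:
        raise ValueError("a correlation map needs at least 2 series")
    entries, zero = {}, {}
    for a, b in combinations(series_set.names, 2):
        cf = cross_correlation(
            series_set.series(a), series_set.series(b), series_set.dt_fs, max_lag_fs
        )
        entries[(a, b)] = cf.extremum()
        zero[(a, b)] = (cf.at_zero_lag(), 0.0)
    return CrossCorrelationMap(list(series_set.names), entries, zero)


def _biased_correlation(x, y, dt_fs: float, max_lag_fs=None) -> CorrelationFunction:
    """Fixed-denominator estimate R(k) = N(k) / (n * sigma_x * sigma_y).

    Defaults to the full lag range |k| <= n-1: the transform of the
    full-range biased autocorrelation is |X(nu)|^2 / (n^2 sigma^2) >= 0 at
    every frequency, which truncated ranges do not guarantee.
    """
    from scipy.signal import correlate

    xc, yc = _prepare(x, y)
    n = xc.size
    L = n - 1 if max_lag_fs is None else _lag_window(n, dt_fs, max_lag_fs)
    full = correlate(yc, xc, mode="full", method="fft")
    num = full[n - 1 - L: n + L]
    denom = n * np.sqrt(np.mean(xc * xc) * np.mean(yc * yc))
    ks = np.arange(-L, L + 1)
    return CorrelationFunction(ks * dt_fs, num / denom, dt_fs)


def cross_power_spectrum(
    x,
    y,
    dt_fs: float | None = None,
    window: str | None = None,
    zero_pad_factor: int = 4,
    max_lag_fs: float | None = None,
) -> SpectralDensity:
    """Cross power spectrum: the Fourier transform of the cross-correlation.

    ``x`` may be a precomputed :class:`CorrelationFunction`; otherwise the
    biased, mean-subtracted cross-correlation of the two series is formed
    first. An optional Hann window (``window="hann"``) tapers the lag
    record; zero padding (default 4x) refines the frequency grid beyond
    the intrinsic resolution 1/(c*T). The unpadded, unwindowed transform
    is exactly invertible back to the correlation function.
    """
    if isinstance(x, CorrelationFunction):
        corr = x
    else:
        if dt_fs is None:
            raise ValueError("dt_fs is required when passing raw series")
        if np.asarray(x).size < 8:
            raise ValueError("need at least 8 samples for a spectrum")
        corr = _biased_correlation(x, y, dt_fs, max_lag_fs)

    r = corr.values
    m = r.size
    L = (m - 1) // 2
    if window == "hann":
        r = r * np.hanning(m)
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    n_fft = m * int(zero_pad_factor)

    # S(nu_j) = sum_k R(tau_k) exp(-2 pi i nu_j tau_k), tau_k = (k - L) dt
    raw = np.fft.fft(r, n_fft)
    grid = np.fft.fftfreq(n_fft)
    full = raw * np.exp(2j * np.pi * grid * L)
    freqs_cm1 = grid / (corr.dt_fs * SPEED_OF_LIGHT_CM_PER_FS)

    keep = grid >= 0
    res = 1.0 / (SPEED_OF_LIGHT_CM_PER_FS * n_fft * corr.dt_fs)
    order = np.argsort(freqs_cm1[keep])
    return SpectralDensity(
        frequencies_cm1=freqs_cm1[keep][order],
        values=full[keep][order],
        resolution_cm1=res,
        _full_values=raw if window in (None, "none") else None,
        _full_freqs=freqs_cm1,
        _lag_count=m,
        _dt_fs=corr.dt_fs,
    )


def spectral_resolution(T_total_fs: float) -> float:
    """Frequency resolution (cm^-1) of a record of length T: nu = 1/(c*T)."""
    if T_total_fs <= 0:
        raise ValueError("record length must be positive")
    return 1.0 / (SPEED_OF_LIGHT_CM_PER_FS * T_total_fs)


def dominant_frequencies(
    spectrum: SpectralDensity,
    n_peaks: int = 5,
    min_separation_cm1: float | None = None,
) -> list:
    """Strongest local maxima of |S(nu)|, as (frequency_cm1, magnitude) pairs.

    Peaks closer than ``min_separation_cm1`` (default: the spectral
    resolution) are merged keeping the larger; a flat spectrum yields an
    empty list.
    """
    from scipy.signal import find_peaks

    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    mag = spectrum.magnitude()
    if np.ptp(mag) == 0.0:
        return []
    idx, _ = find_peaks(mag)
    if idx.size == 0:
        return []
    if min_separation_cm1 is None:
        min_separation_cm1 = spectrum.resolution_cm1
    # strongest first; drop peaks within min_separation of an accepted one
    kept: list[int] = []
    for i in idx[np.argsort(mag[idx])[::-1]]:
        if all(
            abs(spectrum.frequencies_cm1[i] - spectrum.frequencies_cm1[j]) >= min_separation_cm1
            for j in kept
        ):
            kept.append(i)
        if len(kept) == n_peaks:
            break
    return [(float(spectrum.frequencies_cm1[i]), float(mag[i])) for i in kept]
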