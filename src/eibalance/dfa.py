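"""Long-range temporal correlations of oscillation amplitude envelopes.

The chain is: zero-phase band-pass filter (extended alpha band 6-13 Hz by
default), amplitude envelope as the magnitude of the analytic signal, then
detrended fluctuation analysis (DFA-1) of the envelope. The DFA exponent
alpha is the slope of log10 mean fluctuation versus log10 window size over
log-spaced windows; alpha = 0.5 marks an uncorrelated signal, alpha > 0.5
persistent long-range temporal correlations.

The estimator follows scikit-learn conventions: parameters in the
constructor, ``fit`` on an envelope (or (n_samples, n_channels) stack of
envelopes), fitted attributes with trailing underscores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

EXTENDED_ALPHA = (6.0, 13.0)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band in Hz."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError(f"invalid band [{self.low}, {self.high}] Hz")


@dataclass
class DfaResult:
    """DFA output: fitted exponent plus the full fluctuation function."""

    exponent_alpha: float
    window_sizes_s: np.ndarray
    fluctuations: np.ndarray
    fit_range_s: tuple[float, float]
    fit_r2: float
    band: BandSpec | None = None
    roi: str = ""


def bandpass(x: np.ndarray, band: BandSpec | tuple[float, float], fs: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (order ``order``, applied forward
    and backward with ``sosfiltfilt``, so the effective attenuation is
    doubled and the phase response is flat).

    The first and last second carry filter edge transients; callers doing
    window statistics may wish to exclude them.
    """
    if isinstance(band, tuple):
        band = BandSpec(*band)
    if band.high >= fs / 2:
        raise ValueError(f"band edge {band.high} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def envelope(filtered: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic (Hilbert) signal.

    The FFT is zero-padded to the next fast length and truncated back, which
    only perturbs a few edge samples.
    """
    from scipy.fft import next_fast_len

    filtered = np.asarray(filtered, float)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("non-finite values in filtered signal")
    n = filtered.shape[0]
    analytic = sps.hilbert(filtered, N=next_fast_len(n), axis=0)[:n]
    return np.abs(analytic)


def _dfa_window_sizes(fs: float, window_range_s: tuple[float, float],
                      n_windows: int) -> np.ndarray:
    sizes = np.geomspace(window_range_s[0], window_range_s[1], n_windows)
    samples = np.unique(np.round(sizes * fs).astype(int))
    return samples[samples >= 4]


class DFA(BaseEstimator):
    """Detrended fluctuation analysis (order-1 detrending).

    Parameters
    ----------
    fs : sampling rate in Hz.
    window_range_s : (min, max) window sizes in seconds for both the
        fluctuation function and the log-log fit (default 5-30 s: the
        smallest window must clear the band-pass-induced envelope
        decorrelation so that uncorrelated surrogates read ~0.5, and the
        largest stays below 1/4 of the 120-s minimum recording).
    n_windows : number of log-spaced window sizes (default 15).
    overlap_frac : fractional overlap of successive windows (default 0.5).

    Attributes (after ``fit``)
    --------------------------
    exponents_ : per-channel DFA exponent alpha.
    window_sizes_s_, fluctuations_ : the fluctuation function F(t).
    fit_r2_ : per-channel R^2 of the log-log regression.
    """

    def __init__(self, fs: float = 1250.0,
                 window_range_s: tuple[float, float] = (5.0, 30.0),
                 n_windows: int = 15, overlap_frac: float = 0.5):
        self.fs = fs
        self.window_range_s = window_range_s
        self.n_windows = n_windows
        self.overlap_frac = overlap_frac

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        one_d = X.ndim == 1
        if one_d:
            X = X[:, None]
        sizes = _dfa_window_sizes(self.fs, self.window_range_s, self.n_windows)
        min_len = 2 * sizes[-1]
        if X.shape[0] < min_len:
            raise ValueError(
                f"signal of {X.shape[0]} samples shorter than required minimum "
                f"{min_len} (2x the largest window)"
            )
        profile = np.cumsum(X - X.mean(axis=0, keepdims=True), axis=0)
        flucts = np.empty((len(sizes), X.shape[1]))
        for i, w in enumerate(sizes):
            flucts[i] = _window_rms(profile, w, self.overlap_frac)
        log_t = np.log10(sizes / self.fs)
        self.window_sizes_s_ = sizes / self.fs
        self.fluctuations_ = flucts
        exps = np.full(X.shape[1], np.nan)
        r2 = np.full(X.shape[1], np.nan)
        for c in range(X.shape[1]):
            f = flucts[:, c]
            if np.any(f <= 0) or not np.all(np.isfinite(f)):
                warnings.warn(
                    "degenerate envelope (zero fluctuation); DFA exponent undefined",
                    stacklevel=2,
                )
                continue
            log_f = np.log10(f)
            slope, intercept = np.polyfit(log_t, log_f, 1)
            pred = slope * log_t + intercept
            ss_res = np.sum((log_f - pred) ** 2)
            ss_tot = np.sum((log_f - log_f.mean()) ** 2)
            exps[c] = slope
            r2[c] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.exponents_ = exps
        self.fit_r2_ = r2
        return self

    def result(self, channel: int = 0, band: BandSpec | None = None,
               roi: str = "") -> DfaResult:
        return DfaResult(
            exponent_alpha=float(self.exponents_[channel]),
            window_sizes_s=self.window_sizes_s_,
            fluctuations=self.fluctuations_[:, channel],
            fit_range_s=tuple(self.window_range_s),
            fit_r2=float(self.fit_r2_[channel]),
            band=band,
            roi=roi,
        )


def _window_rms(profile: np.ndarray, w: int, overlap_frac: float) -> np.ndarray:
    """Mean over windows of the RMS of the linearly detrended profile."""
    n = profile.shape[0]
    step = max(int(round(w * (1.0 - overlap_frac))), 1)
    starts = np.arange(0, n - w + 1, step)
    # windows: (n_win, w, n_channels)
    idx = starts[:, None] + np.arange(w)[None, :]
    seg = profile[idx]
    # least-squares linear detrend per window via precomputed projection
    t = np.arange(w, dtype=float)
    t -= t.mean()
    denom = np.sum(t * t)
    mean = seg.mean(axis=1, keepdims=True)
    slope = np.einsum("j,ijc->ic", t, seg) / denom
    resid = seg - mean - slope[:, None, :] * t[None, :, None]
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return rms.mean(axis=0)


def dfa(env: np.ndarray, fs: float,
        window_range_s: tuple[float, float] = (5.0, 30.0),
        n_windows: int = 15, overlap_frac: float = 0.5,
        band: BandSpec | None = None, roi: str = "") -> DfaResult:
    """Functional wrapper around :class:`DFA` for a single envelope."""
    est = DFA(fs=fs, window_range_s=window_range_s, n_windows=n_windows,
              overlap_frac=overlap_frac).fit(env)
    return est.result(0, band=band, roi=roi)


def band_envelope(x: np.ndarray, band: BandSpec | tuple[float, float],
                  fs: float) -> np.ndarray:
    """Band-pass then amplitude envelope."""
    return envelope(bandpass(x, band, fs))


def dfa_sweep(x: np.ndarray, fs: float, f_start: float = 1.0,
              f_stop: float = 44.0, f_step: float = 1.0,
              bandwidth: float | None = None,
              **dfa_kwargs) -> list[DfaResult]:
    """DFA across a sweep of contiguous bands [f, f + bandwidth).

    By default bands are 1 Hz wide starting at every integer frequency from
    ``f_start`` to ``f_stop`` inclusive.
    """
    bw = f_step if bandwidth is None else bandwidth
    results = []
    for lo in np.arange(f_start, f_stop + f_step / 2, f_step):
        band = BandSpec(float(lo), float(lo + bw), label=f"{lo:g}-{lo + bw:g}Hz")
        env = band_envelope(x, band, fs)
        results.append(dfa(env, fs, band=band, **dfa_kwargs))
    return results
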