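"""Parameterize a power spectrum into aperiodic and periodic components.

Over a gamma-range window (30-48 Hz by default) the log10 power spectrum is
modelled as a straight line in log10 frequency (the aperiodic component,
whose negative slope is the aperiodic exponent chi) plus up to ``max_peaks``
Gaussian peaks (periodic components). The fit iterates: a robust initial
line fit that down-weights peak bins, Gaussian extraction from the
flattened residual (largest first, stopping below a relative-height floor),
then a final line refit on the peak-subtracted spectrum. Goodness of fit
R^2 is computed on log10 power; fits with R^2 < 0.8 are flagged as
rejected, mirroring the subject-exclusion rule of the analysis.

No spectral 'knee' is fitted: over a 0.2-decade window a knee parameter is
unidentifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

GAMMA_RANGE = (30.0, 48.0)
R2_ACCEPT = 0.8


@dataclass
class AperiodicFitResult:
    """Aperiodic line + periodic peaks with acceptance flag."""

    offset: float
    exponent_chi: float
    peaks: list[tuple[float, float, float]]  # (center Hz, height log10, width Hz)
    r2: float
    fit_range: tuple[float, float]
    accepted: bool


def _gaussian(f, center, height, width):
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


class SpectralModel(BaseEstimator):
    """Aperiodic-plus-peaks spectral model (scikit-learn conventions).

    Parameters
    ----------
    f_range : (low, high) Hz fitting window, default (30, 48).
    max_peaks : maximum number of Gaussian peaks, default 2.
    min_peak_height : minimum peak height in log10-power units, default 0.05.
    peak_threshold_sd : relative detection floor in units of the robust SD
        of the flattened spectrum (default 2.0), so spectral noise is not
        mistaken for periodic structure.
    peak_width_limits : (min, max) Gaussian SD in Hz, default (1, 4);
        widths beyond ~1/4 of the 18-Hz window are indistinguishable from
        the aperiodic component.
    r2_accept : acceptance threshold on log10-power R^2, default 0.8.

    ``fit(freqs, power)`` sets ``offset_``, ``exponent_`` (chi, the negative
    log-log slope), ``peaks_``, ``r2_`` and ``accepted_``.
    """

    def __init__(self, f_range=GAMMA_RANGE, max_peaks: int = 2,
                 min_peak_height: float = 0.05, peak_threshold_sd: float = 2.0,
                 peak_width_limits=(1.0, 4.0), r2_accept: float = R2_ACCEPT):
        self.f_range = f_range
        self.max_peaks = max_peaks
        self.min_peak_height = min_peak_height
        self.peak_threshold_sd = peak_threshold_sd
        self.peak_width_limits = peak_width_limits
        self.r2_accept = r2_accept

    def fit(self, X, y=None):
        freqs = np.asarray(X, float)
        power = np.asarray(y, float)
        sel = (freqs >= self.f_range[0]) & (freqs <= self.f_range[1])
        if sel.sum() < 5:
            raise ValueError(
                f"fewer than 5 bins inside fit range {self.f_range}"
            )
        f = freqs[sel]
        p = power[sel]
        if np.any(p <= 0):
            raise ValueError("non-positive power inside fit range")
        lx = np.log10(f)
        ly = np.log10(p)

        slope, intercept = self._robust_line(lx, ly)
        resid = ly - (intercept + slope * lx)
        robust_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        floor = max(self.min_peak_height, self.peak_threshold_sd * robust_sd)
        peaks: list[tuple[float, float, float]] = []
        for _ in range(self.max_peaks):
            pk = self._extract_peak(f, resid - _sum_gaussians(f, peaks), floor)
            if pk is None:
                break
            peaks.append(pk)
        model_peaks = _sum_gaussians(f, peaks)
        # final line refit on peak-free bins only: a truncated edge peak is
        # never modelled perfectly, and its leftover residual would tilt a
        # refit that uses every bin
        clean = model_peaks < 0.01
        if clean.sum() >= max(5, int(0.3 * len(lx))):
            slope, intercept = np.polyfit(lx[clean], (ly - model_peaks)[clean], 1)
        else:
            slope, intercept = np.polyfit(lx, ly - model_peaks, 1)
        model = intercept + slope * lx + model_peaks
        ss_res = float(np.sum((ly - model) ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

        self.freqs_ = f
        self.offset_ = float(intercept)
        self.exponent_ = float(-slope)
        self.peaks_ = peaks
        self.r2_ = float(r2)
        self.accepted_ = bool(r2 >= self.r2_accept)
        return self

    def _robust_line(self, lx, ly):
        """Line fit that ignores positive (peak) residuals.

        Peaks only add power, so the line is refit iteratively on the bins
        at or below the running median residual — a lower-envelope fit that
        stays anchored even when a peak covers a third of the window.
        """
        slope, intercept = np.polyfit(lx, ly, 1)
        for _ in range(3):
            resid = ly - (intercept + slope * lx)
            keep = resid <= np.median(resid) + 1e-12
            if keep.sum() < 3:
                break
            slope, intercept = np.polyfit(lx[keep], ly[keep], 1)
        return slope, intercept

    def _extract_peak(self, f, resid, floor):
        i = int(np.argmax(resid))
        height = resid[i]
        if height < floor:
            return None
        wlo, whi = self.peak_width_limits
        guess = [f[i], height, np.clip(2.0, wlo, whi)]
        bounds = ([f[0], floor / 2, wlo],
                  [f[-1], np.inf, whi])
        try:
            popt, _ = curve_fit(_gaussian, f, resid, p0=guess, bounds=bounds,
                                maxfev=2000)
        except RuntimeError:
            warnings.warn("peak fit did not converge; skipping peak", stacklevel=2)
            return None
        if popt[1] < floor:
            return None
        return tuple(float(v) for v in popt)

    def result(self) -> AperiodicFitResult:
        return AperiodicFitResult(
            offset=self.offset_,
            exponent_chi=self.exponent_,
            peaks=self.peaks_,
            r2=self.r2_,
            fit_range=tuple(self.f_range),
            accepted=self.accepted_,
        )


def _sum_gaussians(f, peaks):
    out = np.zeros_like(f, dtype=float)
    for center, height, width in peaks:
        out += _gaussian(f, center, height, width)
    return out


def fit_aperiodic(spec, f_range=GAMMA_RANGE, max_peaks: int = 2,
                  **kwargs) -> AperiodicFitResult:
    """Fit a :class:`eibalance.spectral.PowerSpectrum` (or freqs/power pair).

    Returns the gamma-range aperiodic exponent with its acceptance flag.
    """
    if hasattr(spec, "freqs"):
        freqs, power = spec.freqs, spec.power
    else:
        freqs, power = spec
    est = SpectralModel(f_range=f_range, max_peaks=max_peaks, **kwargs)
    est.fit(freqs, power)
    return est.result()


def aperiodic_region(region_spectrum, f_range=GAMMA_RANGE,
                     **kwargs) -> AperiodicFitResult:
    """Fit the region-average spectrum (one fit per region, not a mean of
    per-ROI exponents). A rejected fit (R^2 below threshold) is returned
    with ``accepted=False``; downstream tables record it as missing."""
    return fit_aperiodic(region_spectrum, f_range=f_range, **kwargs)
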