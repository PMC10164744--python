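"""Per-ROI power spectra, region averaging, and moving-mean smoothing.

Spectra are computed per 4096-sample epoch with a plain discrete Fourier
transform (rectangular window by default; a Hann taper is available),
averaged across epochs, and restricted to 1-48 Hz. At the decimated rate of
312.5 Hz the bin spacing is 312.5/4096 = 0.0763 Hz. Noise reduction is a
centred 20-bin moving mean (a span of ~1.5 Hz) with shrinking windows at
the grid edges.

Power normalization: one-sided amplitude^2 per bin, i.e. the per-bin values
sum to the mean squared amplitude of the epoch (Parseval), with interior
bins carrying the doubled one-sided contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

SPECTRUM_RANGE = (1.0, 48.0)


@dataclass
class PowerSpectrum:
    """Frequency grid plus power values, per subject and region/ROI."""

    freqs: np.ndarray
    power: np.ndarray
    region: str = ""
    subject_id: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape[0] != self.power.shape[0]:
            raise ValueError("freqs and power length mismatch")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("negative power values")


def power_spectrum(epochs: np.ndarray, fs: float, f_range=SPECTRUM_RANGE,
                   taper: str = "boxcar") -> list[PowerSpectrum]:
    """Epoch-averaged power spectrum per ROI.

    ``epochs`` is (n_epochs, epoch_len, n_rois) from :func:`eibalance.io.epoch`
    (a 2-D (n_epochs, epoch_len) array is treated as a single ROI). Returns
    one :class:`PowerSpectrum` per ROI on the grid with spacing
    ``fs / epoch_len`` restricted to ``f_range``.
    """
    epochs = np.asarray(epochs, float)
    if epochs.ndim == 2:
        epochs = epochs[:, :, None]
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, epoch_len, n_rois)")
    n_ep, n, n_rois = epochs.shape
    if taper == "boxcar":
        win = np.ones(n)
    elif taper == "hann":
        win = np.hanning(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    # normalization: sum of one-sided power over all bins = mean square
    # (window power compensated; reduces to 1/n^2 for the boxcar)
    scale = 1.0 / (n * np.sum(win**2))
    spec = np.fft.rfft(epochs * win[None, :, None], axis=1)
    p = (np.abs(spec) ** 2) * scale
    p[:, 1:] *= 2.0
    if n % 2 == 0:
        p[:, -1] /= 2.0
    p = p.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    return [PowerSpectrum(freqs[sel], p[sel, r]) for r in range(n_rois)]


def full_power_spectrum(epochs: np.ndarray, fs: float, taper: str = "boxcar"):
    """Like :func:`power_spectrum` but on the full 0..Nyquist grid
    (used for Parseval checks)."""
    return power_spectrum(epochs, fs, f_range=(0.0, fs / 2 + 1.0), taper=taper)


def region_average(spectra: dict[str, PowerSpectrum], region) -> PowerSpectrum:
    """Unweighted mean spectrum across the member ROIs of a region set.

    ``spectra`` maps ROI label -> per-ROI spectrum. Missing member ROIs are
    an error listing the absent labels.
    """
    missing = [m for m in region.members if m not in spectra]
    if missing:
        raise ValueError(f"region {region.name!r} missing ROIs: {missing}")
    members = [spectra[m] for m in region.members]
    freqs = members[0].freqs
    for m in members[1:]:
        if m.freqs.shape != freqs.shape or not np.allclose(m.freqs, freqs):
            raise ValueError("member spectra on different frequency grids")
    power = np.mean([m.power for m in members], axis=0)
    return PowerSpectrum(freqs, power, region=region.name,
                         subject_id=members[0].subject_id,
                         smoothed=members[0].smoothed)


def smooth_spectrum(spec: PowerSpectrum, span_bins: int = 20) -> PowerSpectrum:
    """Centred moving mean over ``span_bins`` consecutive bins.

    Edge rule: the window shrinks symmetrically near the grid edges (for an
    even span the window covers ``(span-1)//2`` bins to the left and
    ``span//2`` to the right of the centre bin, clipped at the edges).
    ``span_bins=1`` is the identity.
    """
    if span_bins < 1:
        raise ValueError("span_bins must be >= 1")
    if span_bins == 1:
        return replace(spec, smoothed=True)
    n = len(spec.freqs)
    if span_bins > n:
        raise ValueError(f"span of {span_bins} bins exceeds grid length {n}")
    left = (span_bins - 1) // 2
    right = span_bins // 2
    csum = np.concatenate([[0.0], np.cumsum(spec.power)])
    i = np.arange(n)
    lo = np.clip(i - left, 0, n)
    hi = np.clip(i + right + 1, 0, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(spec, power=out, smoothed=True)
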