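"""Functional excitation/inhibition ratio from windowed amplitude envelopes.

The fE/I statistic asks whether stretches of high oscillation amplitude
carry relatively larger or smaller detrended fluctuations than stretches of
low amplitude. The envelope is cut into 5-s windows; per window w the mean
amplitude A_w is recorded and the window's demeaned envelope, divided by
A_w, is turned into a signal profile (cumulative sum), linearly detrended,
and summarized by its RMS -> the amplitude-normalized fluctuation nF_w.
Then

    fE/I = 1 - Pearson r(A_w, nF_w)

fE/I ~ 1 marks a balanced network, < 1 an inhibition-dominated regime,
> 1 an excitation-dominated one. Because the statistic is meaningless when
the envelope carries no long-range temporal correlations, a value is only
emitted when the envelope's DFA exponent reaches a validity threshold
(0.55 by default; 0.60 as the conservative sensitivity setting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.base import BaseEstimator

DFA_VALIDITY_THRESHOLD = 0.55
CONSERVATIVE_THRESHOLD = 0.60


@dataclass
class FeiResult:
    """Per-signal fE/I output with validity gating."""

    fei: float  # NaN when invalid
    window_amplitudes: np.ndarray
    normalized_fluctuations: np.ndarray
    correlation_r: float
    dfa_exponent: float
    valid: bool
    threshold_used: float
    roi: str = ""


@dataclass
class ExclusionReport:
    """How many ROIs of a region produced no fE/I value (DFA below threshold)."""

    region: str
    n_rois_total: int
    n_rois_excluded: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_rois_excluded <= self.n_rois_total:
            raise ValueError("excluded count outside [0, total]")


def _window_stats(env: np.ndarray, fs: float, window_s: float,
                  overlap_frac: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-window mean amplitudes and amplitude-normalized fluctuations.

    Windows are aligned to the signal start; a trailing partial window is
    discarded. Zero-amplitude windows are dropped with a warning.
    """
    w = int(round(window_s * fs))
    if w < 4:
        raise ValueError("window too short")
    step = max(int(round(w * (1.0 - overlap_frac))), 1)
    starts = np.arange(0, len(env) - w + 1, step)
    if len(starts) < 2:
        raise ValueError(
            f"envelope of {len(env)} samples yields fewer than 2 windows of "
            f"{w} samples"
        )
    seg = env[starts[:, None] + np.arange(w)[None, :]]
    amps = seg.mean(axis=1)
    good = amps > 0
    if not good.all():
        warnings.warn(f"dropping {np.sum(~good)} zero-amplitude windows", stacklevel=2)
        seg, amps = seg[good], amps[good]
        if len(amps) < 2:
            raise ValueError("fewer than 2 usable windows after dropping")
    norm = (seg - amps[:, None]) / amps[:, None]
    profile = np.cumsum(norm, axis=1)
    t = np.arange(w, dtype=float)
    t -= t.mean()
    slope = profile @ t / np.sum(t * t)
    mean = profile.mean(axis=1)
    resid = profile - mean[:, None] - slope[:, None] * t[None, :]
    nf = np.sqrt(np.mean(resid**2, axis=1))
    return amps, nf


class FEI(BaseEstimator):
    """Functional E/I ratio estimator (scikit-learn conventions).

    Parameters
    ----------
    fs : sampling rate of the envelope in Hz.
    window_s : window length in seconds (default 5).
    overlap_frac : fractional window overlap (default 0, non-overlapping).
    threshold : DFA validity threshold (default 0.55).
    correlation : 'pearson' (the original algorithm) or 'spearman' for
        sensitivity analysis.

    ``fit(envelope, dfa_exponent=...)`` sets ``fei_``, ``valid_``,
    ``correlation_r_``, ``window_amplitudes_`` and
    ``normalized_fluctuations_``.
    """

    def __init__(self, fs: float = 1250.0, window_s: float = 5.0,
                 overlap_frac: float = 0.0,
                 threshold: float = DFA_VALIDITY_THRESHOLD,
                 correlation: str = "pearson"):
        self.fs = fs
        self.window_s = window_s
        self.overlap_frac = overlap_frac
        self.threshold = threshold
        self.correlation = correlation

    def fit(self, X, y=None, dfa_exponent: float = np.inf):
        env = np.asarray(X, float).squeeze()
        if env.ndim != 1:
            raise ValueError("FEI.fit expects a single envelope")
        amps, nf = _window_stats(env, self.fs, self.window_s, self.overlap_frac)
        if self.correlation == "pearson":
            r = sstats.pearsonr(amps, nf).statistic
        elif self.correlation == "spearman":
            r = sstats.spearmanr(amps, nf).statistic
        else:
            raise ValueError(f"unknown correlation {self.correlation!r}")
        self.window_amplitudes_ = amps
        self.normalized_fluctuations_ = nf
        self.correlation_r_ = float(r)
        self.dfa_exponent_ = float(dfa_exponent)
        self.valid_ = bool(dfa_exponent >= self.threshold)
        self.fei_ = 1.0 - self.correlation_r_ if self.valid_ else np.nan
        return self

    def result(self, roi: str = "") -> FeiResult:
        return FeiResult(
            fei=self.fei_,
            window_amplitudes=self.window_amplitudes_,
            normalized_fluctuations=self.normalized_fluctuations_,
            correlation_r=self.correlation_r_,
            dfa_exponent=self.dfa_exponent_,
            valid=self.valid_,
            threshold_used=self.threshold,
            roi=roi,
        )


def fei(env: np.ndarray, fs: float, dfa_exponent: float,
        window_s: float = 5.0, threshold: float = DFA_VALIDITY_THRESHOLD,
        **kwargs) -> FeiResult:
    """Functional wrapper around :class:`FEI`."""
    est = FEI(fs=fs, window_s=window_s, threshold=threshold, **kwargs)
    est.fit(env, dfa_exponent=dfa_exponent)
    return est.result()


def fei_region(results: dict[str, FeiResult], region,
               subject_id: str = "") -> tuple[float, ExclusionReport]:
    """Mean fE/I over the valid ROIs of a region.

    Returns NaN (a legal, recorded outcome) when no member ROI is valid —
    e.g. a subject whose both hippocampal ROIs fall below the DFA
    threshold gets no hippocampal fE/I value.
    """
    missing = [m for m in region.members if m not in results]
    if missing:
        raise ValueError(f"region {region.name!r} missing ROI results: {missing}")
    vals = [results[m].fei for m in region.members if results[m].valid]
    n_total = len(region.members)
    report = ExclusionReport(
        region=region.name,
        n_rois_total=n_total,
        n_rois_excluded=n_total - len(vals),
        subject_id=subject_id,
    )
    value = float(np.mean(vals)) if vals else float("nan")
    return value, report


def fei_threshold_sensitivity(envelopes: dict[str, np.ndarray],
                              dfa_exponents: dict[str, float],
                              fs: float, region,
                              thresholds=(DFA_VALIDITY_THRESHOLD,
                                          CONSERVATIVE_THRESHOLD),
                              subject_id: str = "", **kwargs):
    """Region fE/I at each DFA threshold, with exclusion accounting.

    Returns ``{threshold: (region_value, ExclusionReport)}``. Exclusion
    counts are non-decreasing in the threshold by construction.
    """
    out = {}
    for thr in thresholds:
        results = {
            roi: fei(envelopes[roi], fs, dfa_exponents[roi], threshold=thr,
                     **kwargs)
            for roi in region.members
        }
        out[thr] = fei_region(results, region, subject_id=subject_id)
    thrs = sorted(out)
    for lo, hi in zip(thrs, thrs[1:]):
        assert out[hi][1].n_rois_excluded >= out[lo][1].n_rois_excluded
    return out
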