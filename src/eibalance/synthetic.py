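"""Synthetic ROI time series and cohorts with known ground truth.

Each signal is the sum of three components:

* a band-limited oscillation: band-pass-filtered white noise (the carrier)
  multiplied by a slowly varying positive amplitude envelope whose
  long-range temporal correlation structure is controlled by a Hurst
  exponent (exact fractional-Gaussian-noise synthesis via circulant
  embedding);
* an aperiodic 1/f^chi background, generated by shaping white Gaussian
  noise in the frequency domain;
* additive white sensor noise.

An optional ``excitation_bias`` term couples the size of fast envelope
fluctuations to the slow envelope amplitude, which is what moves the
functional E/I ratio away from 1 in a chosen direction: positive bias
shrinks relative fluctuations in high-amplitude stretches (an
excitation-dominated reading, fE/I > 1), negative bias enlarges them
(inhibition-dominated, fE/I < 1). Group presets place healthy-elderly-like
and AD-like subjects at the parameter combinations used throughout the
test-suite: AD-like signals have a theta-shifted oscillation, a lower
envelope Hurst exponent, a flatter aperiodic slope, and positive
excitation bias.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import RoiTimeSeries

#: scale applied to ``excitation_bias`` inside the envelope-coupling map so
#: that, for the default presets, fE/I - 1 is of the same order as the bias.
_BIAS_GAIN = 2.0


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth parameters of one synthetic ROI signal."""

    duration_s: float = 140.0
    fs: float = 1250.0
    osc_center: float = 10.0
    osc_bandwidth: float = 4.0
    envelope_hurst: float = 0.8
    osc_power: float = 1.0
    aperiodic_exponent: float = 1.5
    aperiodic_power: float = 1.0
    white_noise_power: float = 0.05
    excitation_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration_s * self.fs
        if n <= 0 or abs(n - round(n)) > 1e-6:
            raise ValueError("duration_s * fs must be a positive integer")
        if not 0.0 < self.envelope_hurst < 1.0:
            raise ValueError("envelope_hurst must lie in (0, 1)")
        for name in ("osc_power", "aperiodic_power", "white_noise_power"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SignalSpec":
        return cls(**json.loads(s))


# Presets for the hypothesized E-I regimes. The AD-like preset shifts the
# oscillation into theta, lowers the envelope Hurst exponent, flattens the
# aperiodic slope and biases the network toward excitation.
HEALTHY_PRESET = SignalSpec(
    osc_center=10.0, envelope_hurst=0.80, aperiodic_exponent=1.6,
    excitation_bias=-0.20,
)
AD_PRESET = SignalSpec(
    osc_center=7.0, envelope_hurst=0.65, aperiodic_exponent=1.1,
    excitation_bias=0.60,
)
EXCITATION_DOMINATED_PRESET = replace(HEALTHY_PRESET, envelope_hurst=0.65,
                                      excitation_bias=0.60)
INHIBITION_DOMINATED_PRESET = replace(HEALTHY_PRESET, envelope_hurst=0.65,
                                      excitation_bias=-0.40)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: a template spec plus between-subject jitter SDs."""

    label: str
    n_subjects: int
    template: SignalSpec
    jitter_sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """A multi-group cohort with a cognitive-score covariate model.

    ``cognitive_score_model`` is (baseline, slope vs envelope_hurst,
    slope vs aperiodic_exponent, noise SD) on an MMSE-like 0-30 scale.
    """

    groups: tuple[GroupSpec, ...]
    rois: tuple[str, ...] = ("ROI_1", "ROI_2", "ROI_3", "ROI_4")
    cognitive_score_model: tuple[float, float, float, float] = (6.0, 22.0, 2.5, 1.5)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort must contain at least one group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if len(set(self.rois)) != len(self.rois):
            raise ValueError("ROI labels must be unique")


DEFAULT_JITTER_SD = {
    "envelope_hurst": 0.04,
    "aperiodic_exponent": 0.12,
    "osc_center": 0.5,
    "osc_power": 0.15,
    "excitation_bias": 0.05,
}


def default_cohort_spec(n_per_group: int = 20, master_seed: int = 0,
                        duration_s: float = 140.0) -> CohortSpec:
    """Two-group healthy-elderly-like vs AD-like cohort at the preset effects."""
    he = replace(HEALTHY_PRESET, duration_s=duration_s)
    ad = replace(AD_PRESET, duration_s=duration_s)
    return CohortSpec(
        groups=(
            GroupSpec("HE_like", n_per_group, he, dict(DEFAULT_JITTER_SD)),
            GroupSpec("AD_like", n_per_group, ad, dict(DEFAULT_JITTER_SD)),
        ),
        master_seed=master_seed,
    )


def gen_aperiodic_background(n_samples: int, fs: float, exponent: float,
                             power: float, seed) -> np.ndarray:
    """Zero-mean real signal with power spectral density ~ 1/f^exponent.

    White Gaussian noise is shaped in the frequency domain by f^(-exponent/2)
    amplitude scaling above 1 Hz (DC bin zeroed), inverse-transformed, and
    rescaled to the requested variance. Below 1 Hz the spectrum plateaus at
    its 1-Hz level, as neural power spectra do; without the plateau a steep
    exponent would concentrate nearly all variance below 1 Hz and leave the
    gamma range buried under sensor noise.
    """
    if n_samples < 2 or fs <= 0:
        raise ValueError("n_samples must be >= 2 and fs > 0")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = np.maximum(freqs[1:], 1.0) ** (-exponent / 2.0)
    n_r = len(freqs)
    spec = amp * (rng.standard_normal(n_r) + 1j * rng.standard_normal(n_r))
    spec[0] = 0.0
    if n_samples % 2 == 0:
        spec[-1] = spec[-1].real
    x = np.fft.irfft(spec, n=n_samples)
    x -= x.mean()
    sd = x.std()
    if sd > 0 and power > 0:
        x *= np.sqrt(power) / sd
    elif power == 0:
        x = np.zeros(n_samples)
    return x


def gen_fgn(n_samples: int, hurst: float, seed) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    The circulant embedding of the fGn autocovariance is non-negative
    definite for all Hurst exponents in (0, 1), so the synthesis is exact:
    the output is a stationary Gaussian vector with unit variance and the
    fGn autocovariance 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    h2 = 2.0 * hurst
    k = np.arange(n_samples + 1, dtype=float)
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2 n_samples
    m = len(row)
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # guard tiny negative round-off
    coeff = np.sqrt(lam / m)
    z = coeff * (rng.standard_normal(m) + 1j * rng.standard_normal(m))
    x = np.fft.fft(z).real[:n_samples]
    return x


def gen_fgn_envelope(n_samples: int, hurst: float, seed,
                     shift_sd: float = 2.0, floor: float = 0.05) -> np.ndarray:
    """Strictly positive envelope whose DFA exponent approximates ``hurst``.

    Unit-variance fGn is shifted by ``shift_sd`` standard deviations and
    clipped at a small positive floor; the affine map preserves the
    autocorrelation structure (at the default shift the clip touches ~2.3%
    of samples and biases the DFA exponent by < 0.005, quantified in the
    tests). The default shift sets the modulation depth (CV = 1/shift_sd
    = 0.5, close to the Rayleigh CV of empirical narrow-band envelopes):
    a deeper shift weakens the modulation so much that the carrier's own
    envelope noise masks the long-range temporal correlations after
    band-pass filtering.
    """
    x = gen_fgn(n_samples, hurst, seed)
    env = x + shift_sd
    np.clip(env, floor, None, out=env)
    return env


def _slow_amplitude(env: np.ndarray, fs: float, tau_s: float = 5.0) -> np.ndarray:
    """Centred moving average of the envelope over the fE/I window scale."""
    w = max(int(round(tau_s * fs)), 1)
    kernel = np.ones(w) / w
    slow = sps.fftconvolve(env, kernel, mode="same")
    # correct shrinking-window edge normalization
    norm = sps.fftconvolve(np.ones_like(env), kernel, mode="same")
    return slow / norm


def _apply_excitation_bias(env: np.ndarray, fs: float, bias: float,
                           floor: float = 0.05) -> np.ndarray:
    """Couple fast envelope fluctuations to the slow amplitude.

    Deviations of the envelope from its slow (5-s) moving average are
    multiplied by exp(-gain * bias * max(z, 0)), with z the standardized
    slow amplitude: positive bias suppresses fluctuations where the
    envelope runs high, producing a negative amplitude-vs-normalized-
    fluctuation correlation and hence fE/I > 1; negative bias amplifies
    them (fE/I < 1). Only above-mean-amplitude stretches are modulated —
    scaling fluctuations up in *low*-amplitude stretches would drive the
    envelope into the positivity floor, and the resulting clipping
    asymmetry destroys the very correlation being dialled in. The map is
    monotone in ``bias`` over at least [-0.6, +0.8].
    """
    if bias == 0.0:
        return env
    slow = _slow_amplitude(env, fs)
    z = (slow - slow.mean()) / slow.std()
    m = np.exp(-_BIAS_GAIN * bias * np.clip(z, 0.0, 2.0))
    out = slow + (env - slow) * m
    np.clip(out, floor, None, out=out)
    return out


def _bandlimited_carrier(n_samples: int, fs: float, center: float,
                         bandwidth: float, seed) -> np.ndarray:
    low = center - bandwidth / 2.0
    high = center + bandwidth / 2.0
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"oscillation band [{low:.2f}, {high:.2f}] Hz invalid for fs={fs} Hz"
        )
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, white)


#: rate (Hz) at which the slow modulation envelope is synthesized; alpha
#: amplitude envelopes fluctuate below a few Hz, and the DFA fit range
#: (>= 5-s windows) probes frequencies well under this
ENVELOPE_RATE_HZ = 5.0


def _slow_envelope(n: int, fs: float, hurst: float, bias: float,
                   seed) -> np.ndarray:
    """fGn envelope synthesized at the slow envelope rate, upsampled to fs.

    Sampling the fGn at ENVELOPE_RATE_HZ band-limits the modulation the way
    a physical amplitude envelope is band-limited; linear interpolation to
    the signal rate leaves the DFA exponent in the 5-30 s fit range
    untouched (it only smooths scales below ~0.2 s).
    """
    n_env = int(np.ceil(n / fs * ENVELOPE_RATE_HZ)) + 2
    env = gen_fgn_envelope(n_env, hurst, seed)
    env = _apply_excitation_bias(env, ENVELOPE_RATE_HZ, bias)
    t_env = np.arange(n_env) / ENVELOPE_RATE_HZ
    t = np.arange(n) / fs
    return np.interp(t, t_env, env)


def gen_roi_signal(spec: SignalSpec, roi_label: str = "ROI_1",
                   subject_id: str = "", group: str = "") -> RoiTimeSeries:
    """Realize one ROI signal from its ground-truth spec.

    The oscillation is a slow-envelope-modulated band-limited carrier scaled
    to ``osc_power`` variance, summed with the aperiodic background and
    white noise. The returned series records the full spec under
    ``ground_truth``.
    """
    n = spec.n_samples
    ss = np.random.SeedSequence(spec.seed)
    s_carrier, s_env, s_bg, s_white = ss.spawn(4)

    parts = []
    if spec.osc_power > 0:
        carrier = _bandlimited_carrier(n, spec.fs, spec.osc_center,
                                       spec.osc_bandwidth, s_carrier)
        env = _slow_envelope(n, spec.fs, spec.envelope_hurst,
                             spec.excitation_bias, s_env)
        osc = carrier * env
        osc -= osc.mean()
        osc *= np.sqrt(spec.osc_power) / osc.std()
        parts.append(osc)
    if spec.aperiodic_power > 0:
        parts.append(gen_aperiodic_background(n, spec.fs, spec.aperiodic_exponent,
                                              spec.aperiodic_power, s_bg))
    if spec.white_noise_power > 0:
        rng = np.random.default_rng(s_white)
        parts.append(np.sqrt(spec.white_noise_power) * rng.standard_normal(n))
    data = np.sum(parts, axis=0) if parts else np.zeros(n)
    return RoiTimeSeries(
        data=data[:, None],
        fs=spec.fs,
        roi_labels=(roi_label,),
        subject_id=subject_id,
        group=group,
        ground_truth=asdict(spec),
    )


def _subject_seed_seq(master_seed: int, group: str, subject_index: int) -> np.random.SeedSequence:
    # documented splitting rule: CRC32 of the group label keeps streams
    # stable under group reordering
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(group.encode()), int(subject_index)]
    )


def gen_cohort(spec: CohortSpec) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Generate all subjects of a cohort plus the subject table.

    Per subject, template parameters are jittered with the group's Gaussian
    jitter SDs (Hurst clipped to (0.05, 0.95)), one signal is drawn per ROI,
    and the cognitive score follows the linear covariate model of the true
    subject parameters. Everything is deterministic given ``master_seed``;
    per-subject streams derive from (master_seed, CRC32(group), index).
    """
    subjects: list[RoiTimeSeries] = []
    rows = []
    base, b_h, b_chi, noise_sd = spec.cognitive_score_model
    for g in spec.groups:
        for i in range(g.n_subjects):
            ss = _subject_seed_seq(spec.master_seed, g.label, i)
            jit_rng = np.random.default_rng(ss.spawn(1)[0])
            params = asdict(g.template)
            for name, sd in g.jitter_sd.items():
                if sd > 0:
                    params[name] = params[name] + sd * jit_rng.standard_normal()
            params["envelope_hurst"] = float(np.clip(params["envelope_hurst"], 0.05, 0.95))
            params["osc_power"] = max(params["osc_power"], 0.0)
            params["aperiodic_exponent"] = max(params["aperiodic_exponent"], 0.0)
            score = base + b_h * params["envelope_hurst"] + b_chi * params["aperiodic_exponent"]
            if noise_sd > 0:
                score += noise_sd * jit_rng.standard_normal()
            score = float(np.clip(score, 0.0, 30.0))
            subject_id = f"{g.label}_{i:03d}"

            roi_seeds = ss.spawn(len(spec.rois) + 1)[1:]
            cols = []
            subj_spec = None
            for roi_seed, roi in zip(roi_seeds, spec.rois):
                roi_params = dict(params)
                roi_params["seed"] = int(roi_seed.generate_state(1, np.uint32)[0])
                subj_spec = SignalSpec(**roi_params)
                cols.append(gen_roi_signal(subj_spec, roi_label=roi).data[:, 0])
            ts = RoiTimeSeries(
                data=np.column_stack(cols),
                fs=g.template.fs,
                roi_labels=spec.rois,
                subject_id=subject_id,
                group=g.label,
                cognitive_score=score,
                ground_truth={k: v for k, v in asdict(subj_spec).items() if k != "seed"},
            )
            subjects.append(ts)
            rows.append({
                "subject_id": subject_id,
                "group": g.label,
                "cognitive_score": score,
                "envelope_hurst": params["envelope_hurst"],
                "aperiodic_exponent": params["aperiodic_exponent"],
                "osc_center": params["osc_center"],
                "excitation_bias": params["excitation_bias"],
            })
    return subjects, pd.DataFrame(rows)
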