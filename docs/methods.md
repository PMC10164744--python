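# Methods

This note documents the models, parameter choices and numerical decisions
behind `eibalance`, and what the synthetic validation does and does not
establish about real data.

## Analysis chain

Input is a source-space ROI time-series matrix (samples × ROIs, plain text)
with a JSON sidecar (sampling rate, ROI labels, group, optional cognitive
score, optional artifact-segment mask). The chain is:

1. **Artifact excision.** Masked segments are removed and the clean pieces
   concatenated sample-exactly (no filtering across splice points; splice
   locations are recorded so envelope stages can optionally exclude windows
   spanning them — by default they do not). A warning is emitted if less
   than 120 s survives.
2. **Decimation by 4** for spectral analysis only: a 257-tap linear-phase
   FIR low-pass (cutoff 0.8× the target Nyquist, i.e. 125 Hz when going
   1250 → 312.5 Hz) applied by centred convolution — zero-phase for a
   symmetric kernel — then every 4th sample kept. The cutoff protects the
   full 1–48 Hz analysis band; 150 Hz content is attenuated > 40 dB.
3. **Epoching.** The first 10 consecutive non-overlapping 4096-sample
   epochs (13.1 s each at 312.5 Hz). A shorter signal reduces the epoch
   count with a warning.
4. **Spectra.** Per epoch and ROI, a plain rectangular-window DFT;
   squared magnitudes averaged across epochs; grid spacing fs/4096
   (0.0763 Hz at 312.5 Hz); restricted to 1–48 Hz. Normalization is
   one-sided amplitude² per bin (bins sum to the mean square; Parseval is
   tested). A Hann taper is available but not default. Region spectra are
   unweighted means over member ROIs; noise reduction is a centred 20-bin
   moving mean (~1.5 Hz span) with symmetrically shrinking edge windows.
5. **DFA and fE/I** run on the *non-decimated* signal, band-passed to the
   extended alpha band 6–13 Hz with a zero-phase 4th-order Butterworth
   (applied forward-backward), envelope as the magnitude of the analytic
   (Hilbert) signal.
6. **Aperiodic fit** runs on the smoothed region-average spectrum over
   30–48 Hz (one fit per region, not a mean of per-ROI exponents).

## DFA

Standard DFA-1: demean, cumulative sum, per-window linear detrend, RMS per
window, mean across windows per window size; the exponent is the
least-squares slope of log₁₀ F vs log₁₀ t over log-spaced window sizes
(15 sizes, 50% overlap).

**Fit range: 5–30 s.** The amplitude envelope of a 6–13 Hz band is itself
band-limited below ~3.5 Hz, so the envelope of *uncorrelated* noise carries
filter-induced short-range correlations that inflate DFA slopes at small
windows, with a slowly decaying ~1/t correction. Measured on
band-pass-filtered white noise (300 s at 312.5 Hz), a 1-s lower fit bound
yields a null of α ≈ 0.56 — *above* the 0.55 fE/I validity threshold, which
would make the noise gate vacuous. With the 5-s lower bound
(≥ 30 cycles of the 6-Hz band edge) the null reads 0.52 ± 0.03, consistent
with the α = 0.5 interpretation the validity threshold presupposes. The
upper bound of 30 s stays below a quarter of the 120-s minimum recording.
All three settings (range, count, overlap) are config keys. Degenerate
(constant) envelopes produce a warning and an undefined exponent.

With paper-scale recordings (~140–300 s) the per-estimate spread of α is
0.05–0.10; region averaging reduces it.

## fE/I

The envelope is cut into non-overlapping 5-s windows aligned to the signal
start (trailing partial window discarded; overlap is a config key). Per
window, A_w is the mean amplitude; the window's demeaned envelope divided
by A_w is cumulated, linearly detrended, and summarized by its RMS → nF_w.
fE/I = 1 − Pearson r(A_w, nF_w) (rank correlation available as a
sensitivity option). Zero-amplitude windows are dropped with a warning;
fewer than two usable windows is an error. fE/I ∈ [0, 2] by construction
and is invariant to positive rescaling of the envelope.

A value is only emitted when the envelope's DFA exponent reaches the
validity threshold (0.55; 0.60 conservative). Region values are means over
valid ROIs; a subject with no valid ROI in a region receives no value, and
the per-region exclusion count is itself an analysis endpoint.

## Aperiodic (1/f) parameterization

Over 30–48 Hz, log₁₀ power is modelled as a line in log₁₀ frequency plus up
to 2 Gaussian peaks. Numerical decisions, each forced by the narrowness of
the window (0.2 decades):

* no knee (unidentifiable over 0.2 decades);
* the initial robust line is a lower-envelope fit (iteratively refit on
  bins at or below the median residual) — peaks only *add* power;
* peak detection floor = max(0.05 log₁₀ units, 2× the robust SD of the
  flattened spectrum), so spectral noise is not mistaken for structure;
* peak SD bounded to 1–4 Hz — wider Gaussians are degenerate with the line;
* the final line is refit on peak-free bins only, because a truncated
  edge peak is never modelled perfectly and its leftover residual would
  tilt a full-grid refit.

R² is computed on log₁₀ power (the scale of the fit); fits with R² < 0.8
are flagged rejected and become missing values downstream. Exact recovery
(< 10⁻⁶) on noiseless power laws is tested for χ ∈ {0.5 … 3}; under
log-normal spectral noise (SD 0.05 log₁₀ units) bias is < 0.05 and spread
< 0.15. Known limitation: a wide peak (> ~2 Hz SD) centred near a window
edge is not identifiable over 18 Hz, and the R² flag does not always catch
the resulting slope error; the cross-implementation check therefore uses
interior, moderate-width peaks.

## Statistics

Outliers are flagged beyond 3×IQR outside Q1/Q3 (linear-interpolation
quantiles, pinned for reproducibility) per group before testing. Omnibus
differences use Kruskal–Wallis (tie-corrected, χ² p with k−1 df; H = 0 and
p = 1 for all-identical data); pairwise tests are two-sided Mann–Whitney U
against the reference group, reported with pooled mean ranks — exact null
distribution when both n ≤ 8 without ties, tie-corrected normal
approximation otherwise. Pairwise results are reported regardless of
omnibus significance (flagged permissive, matching common clinical
reporting practice). Spearman correlations use exact permutation p for
n ≤ 9 without ties, the t approximation otherwise.

Per-frequency power comparisons form one FDR family per (group-vs-reference)
curve across all bins, corrected by the two-stage Benjamini–Krieger–Yekutieli
step-up procedure at q = 1% (stage-1 BH at q′ = q/(1+q) to estimate m₀,
stage 2 at q′·m/m₀). The mask is cross-checked against statsmodels'
`fdr_tsbky` in the tests; family-wise any-rejection rate under a global
null is ≤ 5% (tested at reduced scale, 200 replicate families of
synthetic spectra rather than full cohorts, which validates the FDR
machinery but not time-series-level nulls).

Smoothed spectra are used for the per-frequency tests (smoothing is the
final spectral step of the chain).

## Synthetic generator

Each ROI signal = oscillation + 1/f^χ background + white noise:

* **Envelope.** Exact fGn (circulant embedding — non-negative definite for
  all H ∈ (0,1), so the covariance is exact) synthesized at a 5-Hz envelope
  rate and linearly interpolated to the signal rate. A physical amplitude
  envelope is band-limited; synthesizing the fGn at the full signal rate
  would put most of its variance at frequencies the band-pass destroys,
  decoupling the measured envelope from the ground truth. The 5–30 s DFA
  fit range probes envelope frequencies well below 5 Hz, so the
  band-limitation does not affect the exponent. Positivity by a 2-SD shift
  and clip at 0.05 (clip fraction 2.3%, envelope-DFA distortion < 0.005,
  both quantified in tests). The resulting modulation CV of 0.5 is close
  to the Rayleigh CV of empirical narrow-band envelopes; a deeper shift
  weakens the modulation until the carrier's own envelope noise masks the
  correlations. The envelope law (shifted Gaussian) is a modelling choice;
  real MEG alpha envelopes are Rayleigh-like, and nothing here validates
  distributional properties of real envelopes.
* **Carrier.** Band-pass-filtered white noise (default 4 Hz wide around
  `osc_center`); the product is rescaled to `osc_power` variance. The
  carrier's envelope noise attenuates the measured DFA exponent relative
  to the generating Hurst exponent by ≈ 0.07–0.1 at default settings —
  recovery tests on the raw envelope are exact; end-to-end recovery tests
  carry this documented attenuation.
* **Background.** White Gaussian noise shaped by f^(−χ/2) above 1 Hz with a
  plateau below 1 Hz (neural spectra flatten at low frequencies; without
  the plateau a χ = 1.6 background normalized to unit variance would have
  gamma-range power below the sensor-noise floor, and group differences in
  gamma slope could not be expressed). Rescaled to `aperiodic_power`.
* **Excitation bias.** fE/I measures an amplitude–fluctuation coupling
  that a plain stochastic envelope does not possess (for any centred
  Gaussian envelope the window mean and window fluctuation are
  uncorrelated by symmetry), so the generator provides it explicitly:
  envelope deviations from the 5-s moving average are scaled by
  exp(−2·bias·max(z, 0)) with z the standardized slow amplitude. Positive
  bias suppresses fluctuations in high-amplitude stretches → fE/I > 1;
  negative bias amplifies them → fE/I < 1. Only above-mean stretches are
  modulated: amplifying fluctuations in *low*-amplitude stretches drives
  the envelope into the positivity floor, and the clipping asymmetry
  destroys the dialled correlation (the map is monotone in bias over at
  least [−0.6, +0.8]).

**Cohorts.** Per subject, template parameters receive Gaussian jitter
(SDs: Hurst 0.04, χ 0.12, centre 0.5 Hz, power 15%, bias 0.05), one signal
is drawn per ROI, and the cognitive score follows
`6 + 22·hurst + 2.5·χ + N(0, 1.5)` clipped to the 0–30 MMSE-like range.
Per-subject seed streams derive from (master seed, CRC32 of group label,
subject index), so cohorts are reproducible and group order does not
matter.

**Presets.** The healthy-elderly-like regime uses a 10-Hz oscillation,
Hurst 0.80, χ = 1.6, bias −0.20 (region fE/I median ≈ 0.85 — healthy
subjects in clinical recordings also sit below 1); the AD-like regime a
theta-shifted 7-Hz oscillation, Hurst 0.65, χ = 1.1, bias +0.60 (fE/I
median ≈ 1.05). These effect sizes are deliberate caricatures sized so
that n = 20/20 cohorts detect every group difference at p < 0.05 in ≥ 90%
of master seeds; they say nothing about clinical effect sizes.

## Problem sizes used in validation

Synthetic validation runs at desk scale by design: 20 realizations of
300-s signals for the DFA null, 100 permutations for the fE/I null,
20 seeds × 10⁵ samples per Hurst value for envelope recovery, 50 spectra
for the cross-implementation check, and 20 master seeds of n = 20/20
cohorts (140-s signals, 4 ROIs) for the group-difference pattern. Passing
these establishes internal consistency and parameter recovery under the
generator's assumptions — stationary signals, Gaussian envelope law,
additive noise — not performance on clinical recordings with artifacts,
nonstationarity, or inter-site differences.

## Known limitations

* The fE/I algorithm's original window overlap and detrending conventions
  are pinned here as non-overlapping windows with linear detrending;
  both are config keys.
* DFA and fE/I windows spanning artifact splice points are retained by
  default (excludable via the recorded splice locations).
* The region label sets ship as the standard AAL parietal/occipital/
  posterior-cingulate and hippocampal labels; a custom `RegionSet` can be
  substituted anywhere.
* No broadband (1–40 Hz) aperiodic fitting is validated; the fit range is
  a config key but claims hold only for the 30–48 Hz default.
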