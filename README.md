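# eibalance

Excitation–inhibition (E–I) balance biomarkers from resting-state
source-space MEG/EEG ROI time series.

Neuronal circuits keep excitatory and inhibitory synaptic drive in a tight
ratio; its disruption is an early event in Alzheimer's disease. E–I balance
cannot be measured directly in humans, but three spectral/temporal signatures
of it can be read out of a resting-state recording:

* **DFA exponent (α)** — long-range temporal correlations of the alpha-band
  (6–13 Hz) amplitude envelope, estimated by detrended fluctuation analysis.
  α = 0.5 marks an uncorrelated envelope; α > 0.5 persistent correlations.
  Maximal α is expected at the balanced (critical) point, so a *drop* in α
  signals imbalance in either direction.
* **fE/I ratio** — `fE/I = 1 − r(A_w, nF_w)`, where `A_w` is the mean
  envelope amplitude in 5-s windows and `nF_w` the amplitude-normalized
  detrended fluctuation of the same windows. fE/I ≈ 1 is balanced,
  < 1 inhibition-dominated, > 1 excitation-dominated. The value is only
  emitted when the envelope's DFA exponent clears a validity threshold
  (0.55 default, 0.60 sensitivity setting).
* **Aperiodic exponent (χ)** — the negative log-log slope of the 30–48 Hz
  power spectrum after removing Gaussian peaks; a flatter slope (lower χ)
  indexes relatively more excitation. Fits with R² < 0.8 are excluded.

The package implements the full analysis chain these biomarkers sit in —
artifact-mask excision, decimation by 4, 10 × 4096-sample epochs, 1–48 Hz
FFT spectra with 20-bin smoothing, region averaging over AAL parieto-occipital
(24 ROIs) and hippocampal (2 ROIs) sets — plus the nonparametric statistics
layer (3×IQR outlier rule, Kruskal–Wallis, pairwise Mann–Whitney U with mean
ranks, two-stage Benjamini–Krieger–Yekutieli FDR at q = 1%, Spearman
correlations with a cognitive score).

Because clinical MEG data are access-restricted, the package ships a
first-class **synthetic cohort generator** with known ground truth: exact
fractional-Gaussian-noise envelopes (circulant embedding) modulating
band-limited carriers, 1/f^χ backgrounds, white sensor noise, and an
excitation-bias term that moves fE/I in a chosen direction. Every analysis
stage is validated by parameter recovery against this generator.

## Worked example

```python
import eibalance as ei

# one healthy-regime ROI signal: alpha envelope with Hurst 0.75, 1/f^1.5
spec = ei.SignalSpec(duration_s=300.0, fs=1250.0, envelope_hurst=0.75,
                     aperiodic_exponent=1.5, seed=7)
ts = ei.gen_roi_signal(spec)

env = ei.band_envelope(ts.data[:, 0], (6.0, 13.0), ts.fs)
alpha = ei.dfa(env, ts.fs).exponent_alpha
fei = ei.fei(env, ts.fs, dfa_exponent=alpha)

dec = ei.decimate_by_4(ts)
spectrum = ei.smooth_spectrum(ei.power_spectrum(ei.epoch(dec), dec.fs)[0])
chi = ei.fit_aperiodic(spectrum)

print(f"DFA alpha = {alpha:.3f}")
print(f"fE/I      = {fei.fei:.3f} (valid={fei.valid})")
print(f"chi       = {chi.exponent_chi:.3f} (R2={chi.r2:.3f})")
```

Output:

```
DFA alpha = 0.678
fE/I      = 0.896 (valid=True)
chi       = 1.557 (R2=0.922)
```

The DFA exponent tracks the generating Hurst exponent (0.75) up to the
attenuation caused by the carrier's own envelope noise (about −0.09 at
these settings, quantified in the tests); fE/I sits slightly below 1 (no
excitation bias was dialled in; a small inhibition-side reading is typical
of multiplicative envelopes); and the gamma-range aperiodic exponent
recovers the generating χ = 1.5 within the single-subject spread
(SD ≈ 0.3 for a 10-epoch single-ROI spectrum).

An end-to-end cohort demo (simulate → analyze → report):

```bash
eibalance demo --seed 0 --n-per-group 5 --out scratch/demo
```

which prints group medians of all three measures, fE/I exclusion counts,
significant per-frequency power ranges, and the cognitive-score correlation
table.

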