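"""Ground-truth recovery and determinism of the synthetic generator."""

import json
from dataclasses import replace

import numpy as np
import pytest

import eibalance as ei
from eibalance.synthetic import (SignalSpec, CohortSpec, GroupSpec,
                                 gen_aperiodic_background, gen_fgn,
                                 gen_fgn_envelope, gen_roi_signal, gen_cohort,
                                 default_cohort_spec, HEALTHY_PRESET)


def periodogram_slope(signals, fs, f_range=(5.0, 40.0)):
    """Oracle: least-squares log-log fit on the averaged periodogram."""
    from scipy import signal as sps

    psds = []
    for x in signals:
        f, p = sps.periodogram(x, fs=fs)
        psds.append(p)
    p = np.mean(psds, axis=0)
    sel = (f >= f_range[0]) & (f <= f_range[1])
    return np.polyfit(np.log10(f[sel]), np.log10(p[sel]), 1)[0]


class TestAperiodicBackground:
    @pytest.mark.parametrize("chi", [0.5, 1.0, 1.5, 2.0])
    def test_spectral_slope_recovery(self, chi):
        sigs = [gen_aperiodic_background(2**15, 312.5, chi, 1.0, s)
                for s in range(50)]
        slope = periodogram_slope(sigs, 312.5)
        assert slope == pytest.approx(-chi, abs=0.15)

    def test_flat_limit(self):
        sigs = [gen_aperiodic_background(2**15, 312.5, 0.0, 1.0, s)
                for s in range(20)]
        assert periodogram_slope(sigs, 312.5) == pytest.approx(0.0, abs=0.1)

    def test_deterministic_and_scaled(self):
        a = gen_aperiodic_background(4096, 250.0, 1.0, 2.0, 9)
        b = gen_aperiodic_background(4096, 250.0, 1.0, 2.0, 9)
        np.testing.assert_array_equal(a, b)
        assert a.var() == pytest.approx(2.0, rel=1e-10)
        assert a.mean() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_aperiodic_background(1, 250.0, 1.0, 1.0, 0)
        with pytest.raises(ValueError):
            gen_aperiodic_background(100, -1.0, 1.0, 1.0, 0)
        with pytest.raises(ValueError):
            gen_aperiodic_background(100, 250.0, -0.5, 1.0, 0)


class TestFgnEnvelope:
    def test_fgn_unit_variance_and_determinism(self):
        x = gen_fgn(50_000, 0.7, 3)
        y = gen_fgn(50_000, 0.7, 3)
        np.testing.assert_array_equal(x, y)
        assert x.var() == pytest.approx(1.0, abs=0.05)
        assert not np.allclose(x, gen_fgn(50_000, 0.7, 4))

    @pytest.mark.parametrize("hurst", [0.5, 0.85])
    def test_envelope_dfa_tracks_hurst(self, hurst):
        vals = [ei.dfa(gen_fgn_envelope(100_000, hurst, s), 312.5).exponent_alpha
                for s in range(6)]
        assert np.mean(vals) == pytest.approx(hurst, abs=0.05)

    def test_positivity(self):
        env = gen_fgn_envelope(20_000, 0.6, 0)
        assert env.min() > 0

    def test_clip_distortion_quantified(self):
        # affine shift-and-clip leaves the DFA exponent essentially unbiased
        errs = []
        for s in range(6):
            raw = gen_fgn(80_000, 0.8, s) + 10.0  # no clipping at huge shift
            clipped = gen_fgn_envelope(80_000, 0.8, s)
            errs.append(ei.dfa(clipped, 312.5).exponent_alpha
                        - ei.dfa(raw, 312.5).exponent_alpha)
        assert abs(np.mean(errs)) < 0.02

    def test_invalid_hurst(self):
        for h in (0.0, 1.0, -0.3):
            with pytest.raises(ValueError):
                gen_fgn_envelope(1000, h, 0)


class TestRoiSignal:
    def test_deterministic_roundtrip(self):
        spec = replace(HEALTHY_PRESET, duration_s=40.0, seed=11)
        a = gen_roi_signal(spec)
        spec2 = SignalSpec.from_json(spec.to_json())
        b = gen_roi_signal(spec2)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.ground_truth == json.loads(spec.to_json())

    def test_osc_band_above_nyquist(self):
        spec = replace(HEALTHY_PRESET, duration_s=10.0, fs=50.0,
                       osc_center=30.0)
        with pytest.raises(ValueError):
            gen_roi_signal(spec)

    def test_no_oscillation_gives_noise_null_dfa(self):
        vals = []
        for s in range(4):
            spec = replace(HEALTHY_PRESET, osc_power=0.0, seed=s)
            ts = gen_roi_signal(spec)
            env = ei.band_envelope(ts.data[:, 0], (6, 13), ts.fs)
            vals.append(ei.dfa(env, ts.fs).exponent_alpha)
        assert 0.4 < np.mean(vals) < 0.6

    def test_healthy_preset_recovery(self):
        """End-to-end: alpha-band DFA and gamma-range exponent recover the
        generating healthy-regime parameters (true Hurst 0.75, chi 1.5)."""
        from eibalance import io as tsio
        from eibalance.spectral import power_spectrum, smooth_spectrum

        dfas, chis = [], []
        for s in range(10):
            spec = replace(HEALTHY_PRESET, envelope_hurst=0.75,
                           aperiodic_exponent=1.5, excitation_bias=0.0, seed=s)
            ts = gen_roi_signal(spec)
            env = ei.band_envelope(ts.data[:, 0], (6, 13), ts.fs)
            dfas.append(ei.dfa(env, ts.fs).exponent_alpha)
            dec = tsio.decimate_by_4(ts)
            spec_roi = power_spectrum(tsio.epoch(dec), dec.fs)[0]
            fit = ei.fit_aperiodic(smooth_spectrum(spec_roi))
            chis.append(fit.exponent_chi)
        assert 0.65 <= np.mean(dfas) <= 0.85
        assert 1.2 <= np.mean(chis) <= 1.8


class TestCohort:
    def test_subject_table_counts(self, tiny_cohort):
        subjects, table = tiny_cohort
        assert len(subjects) == len(table) == 4
        assert set(table["group"]) == {"HE_like", "AD_like"}

    def test_zero_jitter_zero_noise_scores_identical(self):
        he = replace(HEALTHY_PRESET, duration_s=2.0)
        spec = CohortSpec(
            groups=(GroupSpec("a", 3, he, {}), GroupSpec("b", 2, he, {})),
            rois=("R1",),
            cognitive_score_model=(6.0, 22.0, 2.5, 0.0),
            master_seed=0,
        )
        _, table = gen_cohort(spec)
        for _, sub in table.groupby("group"):
            assert sub["cognitive_score"].nunique() == 1

    def test_master_seed_determinism(self, tiny_cohort_spec):
        a, ta = gen_cohort(tiny_cohort_spec)
        b, tb = gen_cohort(tiny_cohort_spec)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert ta.equals(tb)
        other = replace(tiny_cohort_spec, master_seed=8)
        c, _ = gen_cohort(other)
        assert not np.allclose(a[0].data, c[0].data)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(groups=())

    def test_score_tracks_generating_parameters(self, tiny_cohort):
        _, table = tiny_cohort
        # HE-like (higher hurst and chi) must score higher on average
        he = table.loc[table.group == "HE_like", "cognitive_score"].mean()
        ad = table.loc[table.group == "AD_like", "cognitive_score"].mean()
        assert he > ad
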