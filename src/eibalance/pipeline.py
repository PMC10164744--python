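"""Simulate -> analyze -> report orchestration.

``run_simulate`` writes a synthetic cohort to disk (one text matrix + JSON
sidecar per subject, a cohort-level subject table, and a manifest hashing
the configuration and seed). ``run_analyze`` runs the full measurement
chain per subject and ROI — preprocessing, spectra, DFA, fE/I, gamma-range
aperiodic fit — and emits tidy per-subject and group-level tables where
every cell is either a value or an explicit missingness code. ``run_report``
renders a plain-text/markdown summary with group medians, exclusion counts,
significant per-frequency ranges and the cognitive-score correlation table.

Stage errors are logged with subject/ROI context and recorded as missing
values; exclusions never abort a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tsio
from . import synthetic
from .aperiodic import aperiodic_region, GAMMA_RANGE
from .dfa import DFA, band_envelope, BandSpec, EXTENDED_ALPHA
from .fei import FEI, fei_region, DFA_VALIDITY_THRESHOLD, CONSERVATIVE_THRESHOLD
from .regions import RegionSet
from .spectral import power_spectrum, region_average, smooth_spectrum
from .stats import compare_groups, per_frequency_comparison, spearman, FDR_Q

log = logging.getLogger("eibalance")

MISSING_DFA_GATED = "dfa_gated"
MISSING_R2_REJECTED = "r2_rejected"
MISSING_ERROR = "stage_error"


@dataclass
class PipelineConfig:
    """All tunable settings of the pipeline with the documented defaults."""

    n_per_group: int = 20
    duration_s: float = 140.0
    master_seed: int = 0
    decimation_factor: int = 4
    n_epochs: int = 10
    epoch_len: int = 4096
    spectrum_range: tuple[float, float] = (1.0, 48.0)
    smoothing_bins: int = 20
    alpha_band: tuple[float, float] = EXTENDED_ALPHA
    dfa_window_range_s: tuple[float, float] = (5.0, 30.0)
    dfa_n_windows: int = 15
    dfa_overlap: float = 0.5
    fei_window_s: float = 5.0
    fei_threshold: float = DFA_VALIDITY_THRESHOLD
    fei_threshold_sensitivity: float = CONSERVATIVE_THRESHOLD
    gamma_range: tuple[float, float] = GAMMA_RANGE
    r2_accept: float = 0.8
    fdr_q: float = FDR_Q
    outlier_k: float = 3.0
    reference_group: str = "HE_like"

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.duration_s * 1250.0 < self.n_epochs * self.epoch_len * self.decimation_factor:
            raise ValueError("duration too short for the requested epochs")
        lo, hi = self.alpha_band
        if not 0 < lo < hi:
            raise ValueError("invalid alpha band")
        if not 0 < self.fei_threshold <= self.fei_threshold_sensitivity:
            raise ValueError("invalid fE/I thresholds")

    def manifest_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_simulate(config: PipelineConfig, out_dir: str | Path,
                 cohort_spec: synthetic.CohortSpec | None = None) -> pd.DataFrame:
    """Generate and write a cohort; returns the subject table."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort_spec is None:
        cohort_spec = synthetic.default_cohort_spec(
            n_per_group=config.n_per_group, master_seed=config.master_seed,
            duration_s=config.duration_s)
    subjects, table = synthetic.gen_cohort(cohort_spec)
    for ts in subjects:
        tsio.save_subject(ts, out_dir / f"{ts.subject_id}.txt",
                          out_dir / f"{ts.subject_id}.json")
    table.to_csv(out_dir / "subjects.csv", index=False)
    manifest = {
        "config_hash": config.manifest_hash(),
        "master_seed": config.master_seed,
        "n_subjects": len(subjects),
        "rois": list(cohort_spec.rois),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return table


def _load_cohort(cohort_dir: str | Path) -> list[tsio.RoiTimeSeries]:
    cohort_dir = Path(cohort_dir)
    subjects = []
    for mat in sorted(cohort_dir.glob("*.txt")):
        sidecar = mat.with_suffix(".json")
        if sidecar.name == "manifest.json" or not sidecar.exists():
            continue
        subjects.append(tsio.load_subject(mat, sidecar))
    if not subjects:
        raise FileNotFoundError(f"no subjects found in {cohort_dir}")
    return subjects


def analyze_subject(ts: tsio.RoiTimeSeries, config: PipelineConfig,
                    region: RegionSet | None = None) -> dict:
    """All measures for one subject.

    Spectral measures run on the decimated, epoched signal; DFA and fE/I on
    the non-decimated alpha-band envelope, exactly as in the source
    workflow.
    """
    if region is None:
        region = RegionSet("all_rois", ts.roi_labels)
    clean = tsio.apply_artifact_mask(ts)
    out: dict = {"subject_id": ts.subject_id, "group": ts.group,
                 "cognitive_score": ts.cognitive_score, "region": region.name}

    dec = tsio.decimate_by_4(clean)
    epochs = tsio.epoch(dec, n_epochs=config.n_epochs, epoch_len=config.epoch_len)
    per_roi = power_spectrum(epochs, dec.fs, f_range=config.spectrum_range)
    spectra = dict(zip(clean.roi_labels, per_roi))
    reg_spec = region_average(spectra, region)
    smooth = smooth_spectrum(reg_spec, span_bins=config.smoothing_bins)
    out["spectrum_freqs"] = smooth.freqs
    out["spectrum_power"] = smooth.power

    band = BandSpec(*config.alpha_band, label="extended_alpha")
    dfa_vals, fei_results = {}, {}
    dfa_est = DFA(fs=clean.fs, window_range_s=config.dfa_window_range_s,
                  n_windows=config.dfa_n_windows, overlap_frac=config.dfa_overlap)
    for roi in region.members:
        try:
            env = band_envelope(clean.roi(roi), band, clean.fs)
            alpha = float(dfa_est.fit(env).exponents_[0])
            dfa_vals[roi] = alpha
            fei_est = FEI(fs=clean.fs, window_s=config.fei_window_s,
                          threshold=config.fei_threshold)
            fei_results[roi] = fei_est.fit(env, dfa_exponent=alpha).result(roi)
        except Exception:  # exclusion, not abort
            log.exception("subject %s ROI %s failed", ts.subject_id, roi)
    out["dfa"] = float(np.mean(list(dfa_vals.values()))) if dfa_vals else np.nan
    if fei_results and len(fei_results) == len(region.members):
        value, report = fei_region(fei_results, region, subject_id=ts.subject_id)
        out["fei"] = value
        out["n_rois_excluded"] = report.n_rois_excluded
        out["fei_missing"] = "" if np.isfinite(value) else MISSING_DFA_GATED
    else:
        out["fei"] = np.nan
        out["n_rois_excluded"] = len(region.members) - len(fei_results)
        out["fei_missing"] = MISSING_ERROR
    try:
        fit = aperiodic_region(smooth, f_range=config.gamma_range,
                               r2_accept=config.r2_accept)
        out["aperiodic_exponent"] = fit.exponent_chi if fit.accepted else np.nan
        out["aperiodic_r2"] = fit.r2
        out["aperiodic_missing"] = "" if fit.accepted else MISSING_R2_REJECTED
    except Exception:
        log.exception("subject %s aperiodic fit failed", ts.subject_id)
        out["aperiodic_exponent"] = np.nan
        out["aperiodic_r2"] = np.nan
        out["aperiodic_missing"] = MISSING_ERROR
    return out


MEASURES = ("dfa", "fei", "aperiodic_exponent", "n_rois_excluded")


def run_analyze(config: PipelineConfig, cohort_dir: str | Path,
                region: RegionSet | None = None) -> dict:
    """Analyze every subject of an on-disk cohort.

    Returns ``{"subjects": tidy per-subject DataFrame, "comparisons": list
    of GroupComparison, "per_frequency": DataFrame, "correlations":
    DataFrame}``.
    """
    config.validate()
    cohort_dir = Path(cohort_dir)
    results = [analyze_subject(ts, config, region=region)
               for ts in _load_cohort(cohort_dir)]
    subj = pd.DataFrame([{k: v for k, v in r.items()
                          if not isinstance(v, np.ndarray)} for r in results])

    comparisons = []
    groups = sorted(subj["group"].unique())
    for measure in MEASURES:
        by_group = {g: subj.loc[subj["group"] == g, measure].to_numpy()
                    for g in groups}
        ref = config.reference_group if config.reference_group in by_group \
            else groups[0]
        comparisons.append(compare_groups(by_group, measure=measure,
                                          region=results[0]["region"],
                                          reference=ref,
                                          outlier_k=config.outlier_k))

    freqs = results[0]["spectrum_freqs"]
    spectra_by_group = {"freqs": freqs}
    for g in groups:
        spectra_by_group[g] = np.vstack([r["spectrum_power"] for r in results
                                         if r["group"] == g])
    ref = config.reference_group if config.reference_group in groups else groups[0]
    per_freq = per_frequency_comparison(dict(spectra_by_group), ref, q=config.fdr_q)

    corr_rows = []
    for g in groups:
        sub = subj[subj["group"] == g]
        for measure in ("dfa", "fei", "aperiodic_exponent"):
            pair = sub[[measure, "cognitive_score"]].dropna()
            if len(pair) >= 3:
                rho, p = spearman(pair[measure].to_numpy(),
                                  pair["cognitive_score"].to_numpy())
            else:
                rho, p = np.nan, np.nan
            corr_rows.append({"group": g, "measure": measure,
                              "region": results[0]["region"],
                              "n": len(pair), "rho": rho, "p": p})
    return {
        "subjects": subj,
        "comparisons": comparisons,
        "per_frequency": per_freq,
        "correlations": pd.DataFrame(corr_rows),
        "spectra_by_group": spectra_by_group,
    }


def save_results(results: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results["subjects"].to_csv(out_dir / "subjects_measures.csv", index=False)
    results["per_frequency"].to_csv(out_dir / "per_frequency.csv", index=False)
    results["correlations"].to_csv(out_dir / "correlations.csv", index=False)
    rows = []
    for comp in results["comparisons"]:
        base = {"measure": comp.measure, "region": comp.region, "H": comp.h,
                "df": comp.df, "p": comp.p}
        if comp.pairwise:
            for pw in comp.pairwise:
                rows.append({**base, "group_a": pw.group_a, "group_b": pw.group_b,
                             "U": pw.u, "mean_rank_a": pw.mean_rank_a,
                             "mean_rank_b": pw.mean_rank_b, "pairwise_p": pw.p})
        else:
            rows.append(base)
    pd.DataFrame(rows).to_csv(out_dir / "comparisons.csv", index=False)


def run_report(results: dict, out_path: str | Path | None = None) -> str:
    """Render a markdown summary of the analysis tables."""
    from .stats import significant_ranges

    subj = results["subjects"]
    lines = ["# E-I balance analysis report", ""]
    lines.append("## Group summaries (median [IQR])")
    for measure in ("dfa", "fei", "aperiodic_exponent"):
        lines.append(f"### {measure}")
        for g, sub in subj.groupby("group"):
            v = sub[measure].dropna()
            if len(v):
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                lines.append(f"- {g}: {med:.3f} [{q1:.3f}, {q3:.3f}] (n={len(v)})")
            else:
                lines.append(f"- {g}: no values")
    lines.append("")
    lines.append("## fE/I exclusions (ROIs with DFA below threshold)")
    for g, sub in subj.groupby("group"):
        lines.append(f"- {g}: mean excluded ROIs {sub['n_rois_excluded'].mean():.2f}")
    lines.append("")
    lines.append("## Significant per-frequency power differences vs reference")
    pf = results["per_frequency"]
    if len(pf):
        for g in pf["group"].unique():
            ranges = significant_ranges(pf, g)
            if ranges:
                txt = ", ".join(f"{a:.1f}-{b:.1f} Hz" for a, b in ranges)
            else:
                txt = "none"
            lines.append(f"- {g}: {txt}")
    lines.append("")
    lines.append("## Spearman correlations with cognitive score")
    for _, row in results["correlations"].iterrows():
        lines.append(
            f"- {row['group']} {row['measure']}: n={row['n']}, "
            f"rho={row['rho']:.3f}, p={row['p']:.3f}"
            if np.isfinite(row["rho"]) else
            f"- {row['group']} {row['measure']}: n={row['n']}, undefined"
        )
    text = "\n".join(lines) + "\n"
    if out_path is not None:
        Path(out_path).write_text(text)
    return text
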