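"""ROI time-series container, disk formats, and preprocessing.

A subject is stored on disk as a plain-text numeric matrix (samples x ROIs,
whitespace- or comma-delimited) plus a JSON sidecar holding the sampling
rate, ROI labels, group label, optional cognitive score, optional
artifact-segment mask and any ground-truth generation parameters.

Preprocessing follows the resting-state workflow: excise artifact segments
and concatenate the clean pieces, decimate by a fixed factor of 4 with an
anti-alias FIR low-pass, and cut the first 10 non-overlapping 4096-sample
epochs for spectral analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

MIN_DURATION_S = 120.0
EPOCH_LEN = 4096
DECIMATION_FACTOR = 4


@dataclass
class RoiTimeSeries:
    """Multichannel sampled signal with ROI labels and subject metadata.

    ``data`` is a real (n_samples, n_rois) array in arbitrary source
    amplitude units. ``artifact_mask`` lists bad segments as
    ``(start_s, end_s)`` pairs in seconds. ``splice_points_s`` records, in
    seconds of the cleaned signal, where segments were concatenated.
    """

    data: np.ndarray
    fs: float
    roi_labels: tuple[str, ...]
    subject_id: str = ""
    group: str = ""
    cognitive_score: float | None = None
    artifact_mask: tuple[tuple[float, float], ...] = ()
    splice_points_s: tuple[float, ...] = ()
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains NaN or Inf")
        self.roi_labels = tuple(self.roi_labels)
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.roi_labels)} ROI labels for {self.data.shape[1]} columns"
            )
        dur = self.duration_s
        for lo, hi in self.artifact_mask:
            if not (0.0 <= lo < hi <= dur + 1e-9):
                raise ValueError(f"mask segment ({lo}, {hi}) outside [0, {dur:.3f}]")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[0] / self.fs

    def roi(self, label: str) -> np.ndarray:
        return self.data[:, self.roi_labels.index(label)]


def save_subject(ts: RoiTimeSeries, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    """Write the matrix as delimited text and the metadata as JSON.

    Values are written with the shortest representation that round-trips
    float64 exactly.
    """
    import pandas as pd

    pd.DataFrame(ts.data).to_csv(matrix_path, sep=" ", header=False,
                                 index=False)
    meta = {
        "fs": ts.fs,
        "roi_labels": list(ts.roi_labels),
        "subject_id": ts.subject_id,
        "group": ts.group,
        "cognitive_score": ts.cognitive_score,
        "artifact_mask": [list(seg) for seg in ts.artifact_mask],
        "splice_points_s": list(ts.splice_points_s),
        "ground_truth": ts.ground_truth,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def load_subject(matrix_path: str | Path, sidecar_path: str | Path) -> RoiTimeSeries:
    """Load a subject from a text matrix and its JSON sidecar.

    Parsing is locale-independent (dot decimal separator); both whitespace
    and comma delimiters are accepted.
    """
    matrix_path, sidecar_path = Path(matrix_path), Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    try:
        data = np.loadtxt(matrix_path, ndmin=2)
    except ValueError:
        data = np.loadtxt(matrix_path, delimiter=",", ndmin=2)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{matrix_path}: non-finite values in matrix")
    labels = meta["roi_labels"]
    if len(labels) != data.shape[1]:
        raise ValueError(
            f"{sidecar_path}: {len(labels)} ROI labels but matrix has "
            f"{data.shape[1]} columns"
        )
    return RoiTimeSeries(
        data=data,
        fs=float(meta["fs"]),
        roi_labels=tuple(labels),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
        cognitive_score=meta.get("cognitive_score"),
        artifact_mask=tuple(tuple(seg) for seg in meta.get("artifact_mask", [])),
        splice_points_s=tuple(meta.get("splice_points_s", [])),
        ground_truth=meta.get("ground_truth", {}),
    )


def _merge_segments(segments) -> list[tuple[float, float]]:
    """Union of possibly overlapping (start, end) intervals, sorted."""
    segs = sorted((float(a), float(b)) for a, b in segments)
    merged: list[tuple[float, float]] = []
    for lo, hi in segs:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def apply_artifact_mask(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Excise masked bad segments and concatenate the clean remainder.

    Retained samples are copied bit-exactly (no filtering across splice
    points). Splice locations are recorded in ``splice_points_s`` so that
    envelope-based stages may optionally exclude windows spanning them.
    Warns if the cleaned duration falls below 120 s.
    """
    if not ts.artifact_mask:
        return replace(ts)
    merged = _merge_segments(ts.artifact_mask)
    keep = np.ones(ts.n_samples, dtype=bool)
    for lo, hi in merged:
        i0 = int(round(lo * ts.fs))
        i1 = min(int(round(hi * ts.fs)), ts.n_samples)
        keep[i0:i1] = False
    if not keep.any():
        raise ValueError("artifact mask removes the entire signal")
    splices = []
    kept_before = 0
    for lo, hi in merged:
        i0 = int(round(lo * ts.fs))
        kept_before = int(keep[:i0].sum())
        if 0 < kept_before < int(keep.sum()):
            splices.append(kept_before / ts.fs)
    out = replace(
        ts,
        data=ts.data[keep],
        artifact_mask=(),
        splice_points_s=tuple(splices),
    )
    if out.duration_s < MIN_DURATION_S:
        warnings.warn(
            f"cleaned duration {out.duration_s:.1f} s is below {MIN_DURATION_S:.0f} s",
            stacklevel=2,
        )
    return out


def _antialias_fir(fs: float, factor: int, numtaps: int = 257) -> np.ndarray:
    # cutoff at 0.8x the Nyquist of the target rate keeps 1-48 Hz intact
    cutoff = 0.8 * (fs / factor) / 2.0
    return sps.firwin(numtaps, cutoff, fs=fs)


def decimate_by_4(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Anti-alias low-pass filter, then keep every 4th sample.

    The filter is a linear-phase 257-tap FIR applied with centred ('same')
    convolution, which is zero-phase for a symmetric kernel; its cutoff
    sits at 0.8x the target Nyquist.
    """
    factor = DECIMATION_FACTOR
    taps = _antialias_fir(ts.fs, factor)
    if ts.n_samples < len(taps):
        raise ValueError(
            f"signal of {ts.n_samples} samples shorter than the "
            f"{len(taps)}-tap anti-alias filter"
        )
    filtered = sps.fftconvolve(ts.data, taps[:, None], mode="same", axes=0)
    out = filtered[::factor]
    return replace(
        ts,
        data=out,
        fs=ts.fs / factor,
        splice_points_s=ts.splice_points_s,
    )


def epoch(ts: RoiTimeSeries, n_epochs: int = 10, epoch_len: int = EPOCH_LEN) -> np.ndarray:
    """Cut the first ``n_epochs`` consecutive non-overlapping epochs.

    Returns an (n_epochs, epoch_len, n_rois) array. If the signal is too
    short for the requested count the epoch count is reduced with a
    warning; a signal shorter than one epoch is an error.
    """
    available = ts.n_samples // epoch_len
    if available < 1:
        raise ValueError(
            f"signal of {ts.n_samples} samples holds no {epoch_len}-sample epoch"
        )
    if available < n_epochs:
        warnings.warn(
            f"only {available} of {n_epochs} requested epochs available",
            stacklevel=2,
        )
        n_epochs = available
    out = ts.data[: n_epochs * epoch_len]
    return out.reshape(n_epochs, epoch_len, ts.n_rois)
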