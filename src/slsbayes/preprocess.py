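"""Raw-trace pre-processing: from detector time series to one Rayleigh
ratio per concentration level.

A batch SLS run injects buffer, then each concentration in turn, then
buffer again, while the detector records a time series: the signal is a
staircase of plateaus separated by injection transients, contaminated by
spikes (bubbles, particulates) near each injection. The pipeline is

1. ``segment_trace`` — locate the plateaus by robust change-point
   detection (rolling-median jumps), first and last marked as buffer;
2. ``flag_artifacts`` — within each plateau, flag points whose robust
   z-score (deviation from the plateau median scaled by 1.4826·MAD)
   exceeds a threshold, plus a guard band around each flagged point;
3. ``baseline_correct`` — subtract the buffer level (mean of the two
   buffer summaries, or a linear drift interpolation between them);
4. ``summarize_level`` — trimmed median of the surviving points.

Thresholds, window sizes, the guard-band width and the trim fraction are
configuration keys; the defaults are working values chosen to match the
qualitative behaviour described for this class of instrument, not
constants of nature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, median_filter

__all__ = [
    "PreprocessConfig",
    "Segment",
    "SegmentationError",
    "DegenerateSegmentError",
    "segment_trace",
    "flag_artifacts",
    "baseline_correct",
    "summarize_level",
    "clean_trace",
]


class SegmentationError(RuntimeError):
    """Raised when the requested number of plateaus cannot be found."""


class DegenerateSegmentError(RuntimeError):
    """Raised when artifact flagging would discard an entire segment."""


@dataclass(frozen=True)
class PreprocessConfig:
    cp_window: int = 15  # rolling-median window for change-point detection
    cp_z: float = 6.0  # jump threshold in units of robust point noise
    artifact_z: float = 3.5  # robust z-score threshold within a plateau
    guard_frac: float = 0.02  # guard band radius as fraction of segment length
    trim_frac: float = 0.10  # fraction trimmed from each tail of a plateau
    edge_trim: int = 2  # samples dropped at each segment edge (ramp remnants)
    interpolate_baseline: bool = False
    ri_cutoff_mg_per_ml: float = 20.0


@dataclass
class Segment:
    start: int  # inclusive index into the trace
    stop: int  # exclusive
    is_buffer: bool

    def slice(self) -> slice:
        return slice(self.start, self.stop)


def _robust_noise(y: np.ndarray) -> float:
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def segment_trace(
    y: np.ndarray, n_levels: int, config: PreprocessConfig = PreprocessConfig()
) -> list[Segment]:
    """Split a trace into n_levels + 2 plateaus (buffers first and last).

    Jumps of the rolling median larger than ``cp_z`` times the robust
    point noise mark transitions; each transition is refined to the
    sample of largest local step. Raises :class:`SegmentationError` if a
    different number of plateaus is found.
    """
    y = np.asarray(y, dtype=float)
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    w = config.cp_window
    if y.size < (n_levels + 2) * max(2 * w, 5):
        raise SegmentationError(
            f"trace of {y.size} samples is too short for {n_levels + 2} plateaus"
        )
    med = median_filter(y, size=w, mode="nearest")
    jump = np.abs(med[w:] - med[:-w])  # centred at i + w/2
    noise = _robust_noise(y)
    thresh = max(config.cp_z * noise, 1e-12 * max(np.ptp(y), 1.0))
    trans = jump > thresh
    # group contiguous transition zones, refine each to the sharpest step
    boundaries = []
    i = 0
    while i < trans.size:
        if trans[i]:
            j = i
            while j < trans.size and trans[j]:
                j += 1
            lo = max(i, 1)
            hi = min(j + w, y.size - 1)
            steps = np.abs(np.diff(y[lo : hi + 1]))
            boundaries.append(lo + int(np.argmax(steps)) + 1)
            i = j
        else:
            i += 1
    n_seg = len(boundaries) + 1
    if n_seg != n_levels + 2:
        raise SegmentationError(
            f"found {n_seg} plateaus, expected {n_levels + 2} "
            f"(boundaries at {boundaries}, threshold {thresh:.3g})"
        )
    edges = [0, *boundaries, y.size]
    segments = []
    for s in range(n_seg):
        start, stop = edges[s], edges[s + 1]
        t = config.edge_trim if 0 < s else 0
        t2 = config.edge_trim if s < n_seg - 1 else 0
        start2, stop2 = start + t, stop - t2
        if stop2 - start2 < 1:
            raise SegmentationError(f"segment {s} empty after edge trimming")
        segments.append(Segment(start2, stop2, is_buffer=(s == 0 or s == n_seg - 1)))
    return segments


def flag_artifacts(
    y_seg: np.ndarray, config: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Boolean mask of points to discard within one plateau.

    A point is flagged when |y − median| / (1.4826·MAD) exceeds
    ``artifact_z``; flagged points are dilated by a guard band of
    ``guard_frac`` of the segment length. Never flags everything — that
    raises :class:`DegenerateSegmentError`.
    """
    y_seg = np.asarray(y_seg, dtype=float)
    n = y_seg.size
    if n < 5:
        raise ValueError(f"segment of {n} points is too short to screen (need >= 5)")
    med = np.median(y_seg)
    dev = np.abs(y_seg - med)
    mad = np.median(dev)
    scale = 1.4826 * mad
    if scale == 0.0:
        z = np.where(dev > 0, np.inf, 0.0)
    else:
        z = dev / scale
    mask = z > config.artifact_z
    guard = int(round(config.guard_frac * n))
    if guard > 0 and mask.any():
        mask = binary_dilation(mask, iterations=guard)
    if mask.all():
        raise DegenerateSegmentError("artifact screening flagged every point")
    return mask


def _trimmed_median(x: np.ndarray, trim_frac: float) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    k = int(np.floor(trim_frac * x.size))
    if x.size - 2 * k < 1:
        k = (x.size - 1) // 2
    return float(np.median(x[k : x.size - k]))


def summarize_level(
    y_seg: np.ndarray,
    mask: np.ndarray | None = None,
    trim_frac: float = 0.10,
) -> float:
    """Trimmed median of the unmasked points of one plateau."""
    y_seg = np.asarray(y_seg, dtype=float)
    if mask is not None:
        y_seg = y_seg[~np.asarray(mask, dtype=bool)]
    if y_seg.size < 1:
        raise ValueError("no unmasked points to summarise")
    return _trimmed_median(y_seg, trim_frac)


def baseline_correct(
    summaries: np.ndarray,
    centers: np.ndarray,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the buffer level from per-segment summaries.

    ``summaries`` and ``centers`` are per-segment (buffers first and
    last). Default baseline is the mean of the two buffer summaries;
    with ``interpolate_baseline`` the baseline drifts linearly in time
    between them. Returns (corrected summaries, baseline per segment).
    """
    summaries = np.asarray(summaries, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if summaries.size < 3:
        raise ValueError("need two buffers and at least one level")
    b0, b1 = summaries[0], summaries[-1]
    if config.interpolate_baseline:
        t0, t1 = centers[0], centers[-1]
        baseline = b0 + (b1 - b0) * (centers - t0) / (t1 - t0)
    else:
        baseline = np.full_like(summaries, 0.5 * (b0 + b1))
    return summaries - baseline, baseline


def clean_trace(
    trace: pd.DataFrame,
    n_levels: int,
    config: PreprocessConfig = PreprocessConfig(),
    detector_id: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline on a raw trace table.

    ``trace`` needs columns ``time_s``, ``intensity`` and (with several
    detectors) ``detector_id``; only the analysis detector (90°) feeds
    the model, chosen by ``detector_id`` or taken as the only one
    present. Returns a per-level table (level, rayleigh summary,
    retained-point count, artifact fraction) and a QC report.
    """
    required = {"time_s", "intensity"}
    if not required.issubset(trace.columns):
        raise ValueError(f"trace is missing columns {sorted(required - set(trace.columns))}")
    if "detector_id" in trace.columns and trace["detector_id"].nunique() > 1:
        if detector_id is None:
            raise ValueError(
                "multiple detectors present; specify detector_id for the 90° channel"
            )
        trace = trace[trace["detector_id"] == detector_id]
    trace = trace.sort_values("time_s")
    t = trace["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")
    y = trace["intensity"].to_numpy(dtype=float)

    segments = segment_trace(y, n_levels, config)
    summaries, centers, flag_frac, counts = [], [], [], []
    for seg in segments:
        ys = y[seg.slice()]
        mask = flag_artifacts(ys, config)
        summaries.append(summarize_level(ys, mask, config.trim_frac))
        centers.append(0.5 * (t[seg.start] + t[seg.stop - 1]))
        flag_frac.append(float(mask.mean()))
        counts.append(int((~mask).sum()))
    corrected, baseline = baseline_correct(
        np.asarray(summaries), np.asarray(centers), config
    )
    levels = pd.DataFrame(
        {
            "level": np.arange(1, n_levels + 1),
            "rayleigh_1_per_cm": corrected[1:-1],
            "n_retained": counts[1:-1],
            "artifact_fraction": flag_frac[1:-1],
        }
    )
    qc = {
        "baseline": baseline.tolist(),
        "buffer_summaries": [summaries[0], summaries[-1]],
        "buffer_corrected": [corrected[0], corrected[-1]],
        "artifact_fraction": flag_frac,
        "segment_bounds": [[s.start, s.stop] for s in segments],
    }
    return levels, qc
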