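"""Automated droplet enumeration from a 1D bright-field detector trace.

The signal of one droplet passing the detection point decomposes into a
plateau (the homogeneous droplet interior) flanked by two narrow meniscus
peaks, riding on the carrier-oil baseline.  Droplets whose cells grew are
darker than empty ones because the grown culture absorbs light, so the
plateau amplitude separates the two classes.

The pipeline here is deliberately parameter-light:

1. detect meniscus spikes by prominence on a lightly smoothed trace;
2. pair consecutive spikes whose enclosed interval is long enough and whose
   interior level differs from the oil baseline (intervals at baseline level
   are oil gaps, not droplets);
3. take the plateau amplitude as the median of the interior with a guard
   margin trimmed at each end;
4. split amplitudes into growth/empty with an Otsu-style two-class
   threshold, surfacing near-threshold droplets as ``ambiguous``.

Indices are 0-based; segment intervals are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .occupancy import OccupancyCount

__all__ = [
    "Trace",
    "DropletSegment",
    "ClassificationResult",
    "otsu_threshold",
    "segment_trace",
    "classify_segments",
    "fluorescence_gate",
    "tally_segments",
]

logger = logging.getLogger(__name__)


@dataclass
class Trace:
    """A 1D detector intensity series."""

    values: np.ndarray
    sample_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass(frozen=True)
class DropletSegment:
    """One droplet located in the trace (half-open [start_idx, end_idx))."""

    start_idx: int
    end_idx: int
    front_peak_idx: int
    back_peak_idx: int
    plateau_amplitude: float
    label: str = "unlabelled"  # empty | growth | ambiguous after classification

    def __post_init__(self) -> None:
        if not (self.start_idx < self.front_peak_idx < self.back_peak_idx <= self.end_idx):
            raise ValueError("segment indices must satisfy start < front < back <= end")


@dataclass
class ClassificationResult:
    segments: list[DropletSegment]
    counts: OccupancyCount
    threshold: float
    n_ambiguous: int
    low_confidence: bool


def _robust_sigma(x: np.ndarray) -> float:
    if len(x) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def otsu_threshold(values: np.ndarray) -> float:
    """Exact two-class between-class-variance maximising threshold.

    Works on the sample values directly rather than a binned histogram —
    droplet runs are a few hundred amplitudes, so the exact search is cheap
    and avoids the bin-edge artifact of histogram Otsu when clusters are
    tight.  Ties across the empty inter-class gap resolve to its midpoint.
    """
    a = np.sort(np.asarray(values, float))
    n = len(a)
    if n < 2 or a[-1] - a[0] <= 0:
        raise ValueError("need at least two distinct values")
    csum = np.cumsum(a)
    k = np.arange(1, n)
    mu0 = csum[:-1] / k
    mu1 = (csum[-1] - csum[:-1]) / (n - k)
    w0 = k / n
    var_between = w0 * (1 - w0) * (mu0 - mu1) ** 2
    var_between[a[1:] == a[:-1]] = -np.inf  # no threshold between equal values
    best = int(np.argmax(var_between))
    return float(0.5 * (a[best] + a[best + 1]))


def segment_trace(
    trace: Trace,
    min_plateau_ms: float = 200.0,
    peak_prominence: float = 0.4,
    margin_ms: float = 100.0,
    oil_level: float | None = None,
    smooth_ms: float = 20.0,
) -> list[DropletSegment]:
    """Segment a bright-field trace into droplets.

    ``peak_prominence`` is in trace intensity units; ``margin_ms`` is trimmed
    off both ends of the inter-peak interval before the plateau median is
    taken (guarding against meniscus shoulders).  The oil baseline is
    estimated from the pre-first-peak samples unless given explicitly.
    Unpaired edge spikes lead to the partial droplet being dropped, with a
    logged count.
    """
    if min_plateau_ms <= 0 or peak_prominence <= 0 or margin_ms < 0:
        raise ValueError("segmentation parameters must be positive")
    v = trace.values
    sr = trace.sample_rate
    min_plateau = max(1, int(round(min_plateau_ms / 1000.0 * sr)))
    margin = int(round(margin_ms / 1000.0 * sr))
    if len(v) < min_plateau + 2:
        return []

    smooth_n = max(1, int(round(smooth_ms / 1000.0 * sr)))
    if smooth_n % 2 == 0:
        smooth_n += 1  # odd window: no half-sample shift of peak positions
    vs = uniform_filter1d(v, smooth_n) if smooth_n > 1 else v
    peaks, _ = find_peaks(vs, prominence=peak_prominence)
    if len(peaks) < 2:
        return []

    # baseline and noise from the lead-in oil region (fall back to trace median)
    pre = v[: max(0, peaks[0] - 2 * smooth_n)]
    if oil_level is None:
        oil = float(np.median(pre)) if len(pre) >= 5 else float(np.median(v))
    else:
        oil = float(oil_level)
    sigma = _robust_sigma(pre) if len(pre) >= 5 else _robust_sigma(v)

    segments: list[DropletSegment] = []
    prev_end = 0
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        if p1 - p0 < min_plateau:
            continue
        interior = v[p0 + margin : p1 - margin + 1]
        if len(interior) < max(1, min_plateau - 2 * margin):
            interior = v[p0 + 1 : p1]
        level = float(np.median(interior))
        # gap-vs-droplet decision against the sampling error of the median
        median_se = 1.2533 * sigma / np.sqrt(len(interior))
        contrast = max(8.0 * median_se, 1e-9 * max(1.0, abs(oil)))
        if abs(level - oil) <= contrast:
            continue  # oil gap between droplets
        edge = max(1, margin // 2)
        start = max(prev_end, p0 - edge, 0)
        end = min(len(v), p1 + edge + 1)
        if not start < p0:  # crowded neighbour; keep invariant start < front
            start = p0 - 1
        segments.append(
            DropletSegment(
                start_idx=int(start),
                end_idx=int(end),
                front_peak_idx=int(p0),
                back_peak_idx=int(p1),
                plateau_amplitude=level,
            )
        )
        prev_end = end

    n_dropped = _count_unpaired_edges(peaks, segments)
    if n_dropped:
        logger.info("segment_trace: dropped %d unpaired edge spike(s)", n_dropped)
    return segments


def _count_unpaired_edges(peaks: np.ndarray, segments: list[DropletSegment]) -> int:
    used: set[int] = set()
    for s in segments:
        used.add(s.front_peak_idx)
        used.add(s.back_peak_idx)
    return int(sum(1 for p in peaks if int(p) not in used))


def classify_segments(
    segments: Sequence[DropletSegment],
    threshold: float | None = None,
    deadband_frac: float = 0.05,
) -> ClassificationResult:
    """Two-class split of plateau amplitudes into growth (dark) and empty.

    With ``threshold=None`` the cut maximises between-class variance on the
    amplitude histogram (Otsu); a user-fixed threshold bypasses that.
    Segments within ``deadband_frac`` of the inter-class gap around the
    threshold are labelled ambiguous and excluded from the tallies.  If the
    amplitudes are effectively unimodal, everything is labelled empty and the
    result is flagged low-confidence.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments to classify")
    amps = np.array([s.plateau_amplitude for s in segments])
    low_confidence = False

    if threshold is None:
        if len(segments) < 2:
            raise ValueError("data-driven thresholding needs at least 2 segments")
        if np.ptp(amps) < 1e-12:
            logger.warning("classify_segments: amplitudes unimodal; flagging low confidence")
            labelled = [replace(s, label="empty") for s in segments]
            counts = OccupancyCount(n_total=len(segments), n_growth=0)
            return ClassificationResult(labelled, counts, float(amps[0]), 0, True)
        thr = otsu_threshold(amps)
    else:
        thr = float(threshold)

    lo_mask = amps < thr
    if threshold is None and (not lo_mask.any() or lo_mask.all()):
        logger.warning("classify_segments: one-sided split; flagging low confidence")
        low_confidence = True
    mu_lo = amps[lo_mask].mean() if lo_mask.any() else thr
    mu_hi = amps[~lo_mask].mean() if (~lo_mask).any() else thr
    gap = mu_hi - mu_lo
    if threshold is None and gap > 0:
        pooled = np.sqrt(
            (np.var(amps[lo_mask]) * lo_mask.sum() + np.var(amps[~lo_mask]) * (~lo_mask).sum())
            / len(amps)
        )
        if gap < 2.0 * pooled:
            logger.warning("classify_segments: classes poorly separated; low confidence")
            low_confidence = True

    deadband = deadband_frac * gap
    labelled: list[DropletSegment] = []
    n_growth = n_empty = n_amb = 0
    for s, a in zip(segments, amps):
        if deadband > 0 and abs(a - thr) < deadband:
            labelled.append(replace(s, label="ambiguous"))
            n_amb += 1
        elif a < thr:
            labelled.append(replace(s, label="growth"))
            n_growth += 1
        else:
            labelled.append(replace(s, label="empty"))
            n_empty += 1
    if n_amb:
        logger.info("classify_segments: %d ambiguous droplet(s) excluded from tallies", n_amb)
    counts = OccupancyCount(n_total=n_growth + n_empty, n_growth=n_growth)
    return ClassificationResult(labelled, counts, thr, n_amb, low_confidence)


def fluorescence_gate(
    segments: Sequence[DropletSegment],
    fluor_trace: Trace,
    threshold: float | str = "auto",
    margin_ms: float = 100.0,
) -> np.ndarray:
    """Flag per-segment fluorescence from a co-registered fluorescence trace.

    Amplitude is the median of the fluorescence channel over the same interior
    window used for the bright-field plateau.  ``threshold="auto"`` flags
    amplitudes more than six robust noise SDs above the channel's dark
    baseline; pass a float for an explicit cut.
    """
    v = fluor_trace.values
    margin = int(round(margin_ms / 1000.0 * fluor_trace.sample_rate))
    amps = np.empty(len(segments))
    for i, s in enumerate(segments):
        interior = v[s.front_peak_idx + margin : s.back_peak_idx - margin + 1]
        if len(interior) == 0:
            interior = v[s.front_peak_idx : s.back_peak_idx + 1]
        amps[i] = np.median(interior)
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        baseline = float(np.median(v))
        sigma = _robust_sigma(v)
        thr = baseline + max(6.0 * sigma, 1e-9)
    else:
        thr = float(threshold)
    return amps > thr


def tally_segments(
    segments: Sequence[DropletSegment], fluor_flags: np.ndarray | None = None
) -> OccupancyCount:
    """Tally classified segments (and optional fluorescence flags) for the stats layer.

    Ambiguous segments are excluded.  ``n_fluor`` counts fluorescent droplets
    and ``n_growth_nonfluor`` growth-positive droplets without fluorescence —
    the two tallies dual-label deconvolution consumes.
    """
    if fluor_flags is not None and len(fluor_flags) != len(segments):
        raise ValueError("one fluorescence flag per segment required")
    n_total = n_growth = n_fluor = n_gnf = 0
    for i, s in enumerate(segments):
        if s.label == "ambiguous":
            continue
        if s.label not in ("growth", "empty"):
            raise ValueError("segments must be classified before tallying")
        n_total += 1
        is_growth = s.label == "growth"
        n_growth += is_growth
        if fluor_flags is not None:
            is_fluor = bool(fluor_flags[i])
            n_fluor += is_fluor
            n_gnf += is_growth and not is_fluor
    if fluor_flags is None:
        return OccupancyCount(n_total=n_total, n_growth=n_growth)
    return OccupancyCount(
        n_total=n_total, n_growth=n_growth, n_fluor=n_fluor, n_growth_nonfluor=n_gnf
    )
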