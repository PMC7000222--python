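"""Spatio-temporal activity statistics.

Covers the four quantification styles applied to FRET-index movies:

* quadrant mean-intensity traces (the cell split into four axis-aligned
  quadrants through its centroid);
* compartmentalization summaries — the high-FRET quadrant (HFQ) is the
  quadrant attaining the global maximum mean FRET_T over the movie, the
  low-FRET quadrant (LFQ) is read at that same time point;
* dominant pulse period via the periodogram of quadratically detrended
  traces;
* sector kymographs: activity versus time and distance from the membrane
  within an angular sector anchored on a membrane arc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import DataError
from .segmentation import CellMaskStack

__all__ = [
    "QuadrantTraceSet",
    "CompartmentSummary",
    "StimulationDelta",
    "PSDResult",
    "SectorKymograph",
    "quadrant_mean_traces",
    "compartment_summary",
    "stimulation_delta",
    "dominant_period",
    "cell_dominant_period",
    "sector_kymograph",
]

QUADRANT_IDS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class QuadrantTraceSet:
    """Per-quadrant mean FRET_T time series.

    ``mean_intensity`` has shape (4, T); entry [q, t] is the arithmetic mean
    of FRET_T over mask∩quadrant pixels of quadrant q+1 at frame t, NaN when
    the quadrant is empty in that frame.
    """

    time_min: np.ndarray
    mean_intensity: np.ndarray
    quadrant_ids: tuple = QUADRANT_IDS

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.mean_intensity.shape != (4, self.time_min.size):
            raise DataError("mean_intensity must have shape (4, T)")


@dataclass(frozen=True)
class CompartmentSummary:
    """Global HFQ maximum and the synchronous LFQ reading."""

    max_fret_hfq: float
    lfq_at_same_time: float
    hfq_id: str
    lfq_id: str
    t_at_max: float


@dataclass(frozen=True)
class StimulationDelta:
    """Per-quadrant change of the trace maximum across a stimulation."""

    delta_by_quadrant: dict
    hfq_id: str
    lfq_id: str
    delta_hfq: float
    delta_lfq: float

    @property
    def hfq_exceeds_lfq(self) -> bool:
        return self.delta_hfq > self.delta_lfq


@dataclass(frozen=True)
class PSDResult:
    """One-sided periodogram with its dominant (maximum-power) component."""

    frequency_grid: np.ndarray      # cycles/min (zero bin excluded)
    power: np.ndarray
    dominant_frequency: float       # cycles/min
    dominant_period_min: float


@dataclass
class SectorKymograph:
    """Mean intensity on a (distance-from-edge × time) grid within a sector."""

    distance_bins_px: np.ndarray
    time_min: np.ndarray
    mean_intensity: np.ndarray      # (n_bins, T)
    arc_length_px: int
    arc_center_index: int
    sector_angle_range: tuple


def quadrant_mean_traces(
    fret_index: np.ndarray,
    quadrants: np.ndarray,
    frame_interval_min: float = 0.5,
) -> QuadrantTraceSet:
    """Mean FRET_T per quadrant per frame (sum of pixel values / pixel count)."""
    fret_index = np.asarray(fret_index, dtype=float)
    quadrants = np.asarray(quadrants)
    if fret_index.shape != quadrants.shape:
        raise DataError("fret_index and quadrant labels must share shape")
    T = fret_index.shape[0]
    means = np.full((4, T), np.nan)
    for t in range(T):
        for q in range(1, 5):
            sel = quadrants[t] == q
            if sel.any():
                means[q - 1, t] = fret_index[t][sel].mean()
    return QuadrantTraceSet(time_min=np.arange(T) * frame_interval_min,
                            mean_intensity=means)


def compartment_summary(traces: QuadrantTraceSet) -> CompartmentSummary:
    """HFQ/LFQ summary of a trace table.

    The HFQ maximum is the global maximum over quadrants and time; ties are
    broken by earliest time, then lowest quadrant index.  The LFQ value is
    the minimum quadrant mean at that same time point.
    """
    vals = traces.mean_intensity
    if np.all(np.isnan(vals)):
        raise DataError("all-NaN trace table")
    best = np.nanmax(vals)
    qs, ts = np.where(vals == best)
    order = np.lexsort((qs, ts))            # earliest time, then lowest quadrant
    q_star, t_star = int(qs[order[0]]), int(ts[order[0]])
    col = vals[:, t_star]
    lfq_val = np.nanmin(col)
    lfq_q = int(np.nanargmin(col))
    return CompartmentSummary(max_fret_hfq=float(best),
                              lfq_at_same_time=float(lfq_val),
                              hfq_id=QUADRANT_IDS[q_star],
                              lfq_id=QUADRANT_IDS[lfq_q],
                              t_at_max=float(traces.time_min[t_star]))


def stimulation_delta(
    traces_pre: QuadrantTraceSet,
    traces_post: QuadrantTraceSet,
) -> StimulationDelta:
    """Change of each quadrant's trace maximum after stimulation.

    HFQ and LFQ are designated from the PRE-stimulation period only (the
    quadrant attaining the pre-period global maximum, and the minimum
    quadrant at that time point); the same designation is then used to read
    off post-stimulation deltas.
    """
    pre_summary = compartment_summary(traces_pre)
    deltas = {}
    for q, qid in enumerate(QUADRANT_IDS):
        pre_max = np.nanmax(traces_pre.mean_intensity[q])
        post_max = np.nanmax(traces_post.mean_intensity[q])
        deltas[qid] = float(post_max - pre_max)
    return StimulationDelta(delta_by_quadrant=deltas,
                            hfq_id=pre_summary.hfq_id,
                            lfq_id=pre_summary.lfq_id,
                            delta_hfq=deltas[pre_summary.hfq_id],
                            delta_lfq=deltas[pre_summary.lfq_id])


def dominant_period(
    trace: np.ndarray,
    frame_interval_min: float = 0.5,
) -> PSDResult:
    """Dominant oscillation period of a uniformly sampled trace.

    A least-squares quadratic trend is subtracted first; the one-sided
    periodogram (rectangular window, no zero padding) is then computed and
    the dominant frequency is the argmax of power with the zero-frequency
    bin excluded.  Ties on maximum power resolve to the lowest frequency.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise DataError("need a 1-D trace of ≥8 samples")
    if np.any(np.isnan(x)):
        raise DataError("trace contains NaN; interpolate or trim first")
    t = np.arange(x.size)
    coeffs = np.polyfit(t, x, 2)
    detrended = x - np.polyval(coeffs, t)
    fs = 1.0 / frame_interval_min               # samples per minute
    freqs, power = signal.periodogram(detrended, fs=fs, window="boxcar",
                                      detrend=False)
    freqs, power = freqs[1:], power[1:]         # exclude the zero bin
    if not np.any(power > 0) or float(np.max(power)) < 1e-12 * max(
            1.0, float(np.mean(detrended**2))):
        raise DataError("no oscillatory power after detrending")
    k = int(np.argmax(power))                   # first max ⇒ lowest frequency
    f_dom = float(freqs[k])
    return PSDResult(frequency_grid=freqs, power=power,
                     dominant_frequency=f_dom,
                     dominant_period_min=1.0 / f_dom)


def cell_dominant_period(traces: QuadrantTraceSet) -> float:
    """Cell-level pulse period: per-quadrant dominant periods averaged."""
    dt = float(traces.time_min[1] - traces.time_min[0])
    periods = []
    for q in range(4):
        row = traces.mean_intensity[q]
        if np.any(np.isnan(row)):
            continue
        try:
            periods.append(dominant_period(row, dt).dominant_period_min)
        except DataError:
            continue
    if not periods:
        raise DataError("no quadrant produced a defined dominant period")
    return float(np.mean(periods))


def _ray_samples(p0: np.ndarray, p1: np.ndarray):
    length = float(np.hypot(*(p1 - p0)))
    tsteps = np.arange(0.0, max(length, 1e-9), 1.0)
    if tsteps[-1] < length:
        tsteps = np.append(tsteps, length)
    direction = (p1 - p0) / length if length > 0 else np.zeros(2)
    return p0[None, :] + tsteps[:, None] * direction[None, :], tsteps


def sector_kymograph(
    fret_index: np.ndarray,
    mask: CellMaskStack,
    arc_center: int | str = "auto-max",
    arc_length_px: int = 40,
    radial_bin_px: float = 1.0,
    membrane_depth_px: float = 5.0,
    boundary_window: int = 5,
    frame_interval_min: float = 0.5,
) -> SectorKymograph:
    """Activity kymograph for a sector anchored on a membrane arc.

    The sector geometry is fixed from the first frame: an arc of
    ``arc_length_px`` boundary pixels centered either at a given boundary
    index or, with ``"auto-max"``, at the boundary position whose inward ray
    shows the highest time-averaged FRET_T within ``membrane_depth_px`` of
    the edge (scores smoothed with a circular moving average of
    ``boundary_window`` boundary points), so pulsed hotspots are found even
    when momentarily dark.  The sector is the union of the
    straight segments from each arc pixel to the centroid; intensities are
    pooled per frame into distance-from-edge bins of ``radial_bin_px``.
    """
    fret_index = np.asarray(fret_index, dtype=float)
    boundary = np.asarray(mask.boundaries[0], dtype=float)
    centroid = np.asarray(mask.centroids[0])
    n_b = len(boundary)
    if arc_length_px > n_b:
        raise DataError(f"arc of {arc_length_px} px exceeds boundary length {n_b}")

    rays = [_ray_samples(p0, centroid) for p0 in boundary]

    if arc_center == "auto-max":
        scores = np.empty(n_b)
        first = fret_index.mean(axis=0)
        for i, (coords, dist) in enumerate(rays):
            sel = dist <= membrane_depth_px
            vals = ndimage.map_coordinates(first, coords[sel].T, order=1,
                                           mode="nearest")
            scores[i] = vals.mean()
        if boundary_window > 1:
            kernel = np.ones(boundary_window) / boundary_window
            scores = np.convolve(np.concatenate([scores, scores, scores]),
                                 kernel, mode="same")[n_b:2 * n_b]
        center_idx = int(np.argmax(scores))
    else:
        center_idx = int(arc_center) % n_b

    half = arc_length_px // 2
    arc_idx = [(center_idx + k) % n_b for k in range(-half, arc_length_px - half)]

    max_d = max(rays[i][1][-1] for i in arc_idx)
    n_bins = max(1, int(np.ceil(max_d / radial_bin_px)))
    T = fret_index.shape[0]
    sums = np.zeros((n_bins, T))
    counts = np.zeros((n_bins, T))
    for i in arc_idx:
        coords, dist = rays[i]
        bins = np.clip((dist / radial_bin_px).astype(int), 0, n_bins - 1)
        for t in range(T):
            vals = ndimage.map_coordinates(fret_index[t], coords.T, order=1,
                                           mode="nearest")
            inside = ndimage.map_coordinates(mask.masks[t].astype(float),
                                             coords.T, order=0) > 0.5
            np.add.at(sums[:, t], bins[inside], vals[inside])
            np.add.at(counts[:, t], bins[inside], 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    centers = (np.arange(n_bins) + 0.5) * radial_bin_px

    def angle(i):
        p = boundary[i] - centroid
        return float(np.arctan2(p[0], p[1]))

    return SectorKymograph(
        distance_bins_px=centers,
        time_min=np.arange(T) * frame_interval_min,
        mean_intensity=means,
        arc_length_px=arc_length_px,
        arc_center_index=center_idx,
        sector_angle_range=(angle(arc_idx[0]), angle(arc_idx[-1])),
    )
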