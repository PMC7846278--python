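"""Network-event detection in wide-field calcium-imaging movies.

Spontaneous network events in the developing cortex appear in wide-field
fluorescence movies as spatially extended, suprathreshold increases of
:math:`\\Delta F/F_0`.  An event is defined as a group of at least
``min_event_size`` voxels (default 300) that exceed a fixed
:math:`\\Delta F/F_0` threshold (default 0.12) and are connected in time
and/or space.  :math:`F_0` is a per-pixel moving average across 500 frames.
Because wide-field optics scatter light, the reported event area is
restricted to pixels that reach 67% of the event's peak amplitude.

Units: times in seconds, distances in micrometres, :math:`\\Delta F/F_0`
as a dimensionless fraction (0.12, not 12%).  Arrays are indexed
``(t, y, x)``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FluorescenceMovie",
    "DffMovie",
    "NetworkEvent",
    "EventCatalog",
    "RegionMask",
    "TracePeakParams",
    "pixel_area_um2",
    "min_mean_frame_area_um2",
    "compute_dff",
    "detect_network_events",
    "restrict_event_area",
    "assign_regions",
    "event_frequency_timecourse",
    "percent_change",
    "detect_trace_peaks",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class FluorescenceMovie:
    """Raw-intensity movie (a.u.), shape (T, H, W)."""

    frames: np.ndarray
    frame_rate_hz: float = 20.0
    pixel_size_um: float = 7.68

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie contains non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("movie contains negative intensities")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame rate and pixel size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz


@dataclass
class DffMovie:
    """Fractional fluorescence change, same shape as the source movie."""

    dff: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    baseline_window_frames: int = 500

    def __post_init__(self) -> None:
        if self.baseline_window_frames < 2:
            raise ValueError("baseline_window_frames must be >= 2")

    @property
    def duration_s(self) -> float:
        return self.dff.shape[0] / self.frame_rate_hz


@dataclass
class NetworkEvent:
    """A spatiotemporally connected suprathreshold component.

    ``voxels`` holds ``(t, y, x)`` index arrays; ``footprint_px`` is the set
    of unique ``(y, x)`` pixels touched by the event.
    """

    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]
    onset_frame: int
    offset_frame: int
    peak_dff: float
    frame_rate_hz: float
    pixel_size_um: float
    restricted_area_um2: float | None = None
    restricted_footprint: np.ndarray | None = None  # (n, 2) of (y, x)
    region: str | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxels[0].size)

    @property
    def duration_s(self) -> float:
        return (self.offset_frame - self.onset_frame + 1) / self.frame_rate_hz

    @property
    def onset_s(self) -> float:
        return self.onset_frame / self.frame_rate_hz

    @property
    def footprint_px(self) -> np.ndarray:
        """Unique (y, x) pixels of the event, shape (n, 2)."""
        yx = np.stack([self.voxels[1], self.voxels[2]], axis=1)
        return np.unique(yx, axis=0)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        t, y, x = self.voxels
        return set(zip(t.tolist(), y.tolist(), x.tolist()))


@dataclass
class EventCatalog:
    events: list[NetworkEvent]
    detection_params: dict = field(default_factory=dict)
    frame_rate_hz: float = 20.0
    pixel_size_um: float = 7.68
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_frame,))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass
class RegionMask:
    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("region mask must be 2D (H, W)")


@dataclass
class TracePeakParams:
    """Parameters of the awake-condition 1D-trace peak detector."""

    lowpass_cutoff_hz: float = 2.0
    prominence: float = 0.05
    min_peak_height: float = 0.05


# --------------------------------------------------------------------------
# worked-example helpers
# --------------------------------------------------------------------------

def pixel_area_um2(pixel_size_um: float, rounding: str = "printed") -> float:
    """Area covered by one pixel.

    ``rounding="printed"`` rounds to the printed integer convention
    (7.68 um -> 59 um^2); ``"exact"`` returns ``pixel_size_um**2``.
    """
    exact = pixel_size_um ** 2
    if rounding == "exact":
        return exact
    if rounding == "printed":
        return float(round(exact))
    raise ValueError(f"unknown rounding mode {rounding!r}")


def min_mean_frame_area_um2(
    min_event_size: int = 300,
    duration_s: float = 1.0,
    frame_rate_hz: float = 20.0,
    pixel_size_um: float = 7.68,
    rounding: str = "printed",
) -> float:
    """Mean per-frame area implied by the voxel-count criterion.

    A ``min_event_size``-voxel event lasting ``duration_s`` covers on
    average ``min_event_size / (duration_s * frame_rate_hz)`` pixels per
    frame; with the default parameters this reproduces 885 um^2.
    """
    px_per_frame = min_event_size / (duration_s * frame_rate_hz)
    return px_per_frame * pixel_area_um2(pixel_size_um, rounding)


# --------------------------------------------------------------------------
# dF/F0
# --------------------------------------------------------------------------

def compute_dff(movie: FluorescenceMovie, window: int = 500) -> DffMovie:
    """Per-pixel ``(F - F0)/F0`` with F0 a centered moving average.

    The window covers frames ``[t - window//2, t + window//2]`` and is
    truncated at the movie edges.  Raises if any F0 value is non-positive
    (which signals an invalid raw movie), naming the first offending pixel.
    """
    T = movie.n_frames
    if T < window:
        raise ValueError(f"movie has {T} frames, shorter than the {window}-frame baseline window")
    F = movie.frames.astype(np.float64, copy=False)
    half = window // 2
    csum = np.cumsum(F, axis=0)
    idx = np.arange(T)
    lo = np.clip(idx - half, 0, None)
    hi = np.clip(idx + half + 1, None, T)
    count = (hi - lo).astype(np.float64)
    # S[hi] - S[lo] with S[0] = 0
    upper = csum[hi - 1]
    lower = np.where(lo[:, None, None] > 0, csum[np.clip(lo - 1, 0, None)], 0.0)
    f0 = (upper - lower) / count[:, None, None]
    bad = f0 <= 0
    if np.any(bad):
        t, y, x = np.argwhere(bad)[0]
        raise ValueError(f"non-positive F0 at pixel (t={t}, y={y}, x={x}); raw movie is invalid")
    dff = ((F - f0) / f0).astype(np.float32)
    return DffMovie(
        dff=dff,
        frame_rate_hz=movie.frame_rate_hz,
        pixel_size_um=movie.pixel_size_um,
        baseline_window_frames=window,
    )


# --------------------------------------------------------------------------
# event detection
# --------------------------------------------------------------------------

def _label_structure(connectivity: str) -> np.ndarray:
    if connectivity == "full":  # 26-connectivity in (t, y, x)
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == "face":  # 6-connectivity
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError(f"unknown connectivity {connectivity!r} (use 'full' or 'face')")


def detect_network_events(
    dff: DffMovie,
    threshold: float = 0.12,
    min_event_size: int = 300,
    connectivity: str = "full",
) -> EventCatalog:
    """Threshold + 3D connected-component definition of network events.

    Voxels below ``threshold`` are zeroed; the remaining voxels are grouped
    by connected-component labeling in (t, y, x); components with at least
    ``min_event_size`` voxels become events.
    """
    arr = dff.dff
    if not np.all(np.isfinite(arr)):
        raise ValueError("dff contains non-finite values")
    mask = arr >= threshold
    labels, n_comp = ndimage.label(mask, structure=_label_structure(connectivity))
    events: list[NetworkEvent] = []
    if n_comp:
        tt, yy, xx = np.nonzero(mask)
        lab = labels[tt, yy, xx]
        counts = np.bincount(lab, minlength=n_comp + 1)
        order = np.argsort(lab, kind="stable")
        tt, yy, xx, lab = tt[order], yy[order], xx[order], lab[order]
        bounds = np.searchsorted(lab, np.arange(1, n_comp + 2))
        for k in range(1, n_comp + 1):
            if counts[k] < min_event_size:
                continue
            s, e = bounds[k - 1], bounds[k]
            vt, vy, vx = tt[s:e], yy[s:e], xx[s:e]
            vals = arr[vt, vy, vx]
            events.append(
                NetworkEvent(
                    voxels=(vt.copy(), vy.copy(), vx.copy()),
                    onset_frame=int(vt.min()),
                    offset_frame=int(vt.max()),
                    peak_dff=float(vals.max()),
                    frame_rate_hz=dff.frame_rate_hz,
                    pixel_size_um=dff.pixel_size_um,
                )
            )
    return EventCatalog(
        events=events,
        detection_params={
            "threshold_dff": threshold,
            "min_event_size": min_event_size,
            "connectivity": connectivity,
        },
        frame_rate_hz=dff.frame_rate_hz,
        pixel_size_um=dff.pixel_size_um,
        duration_s=dff.duration_s,
    )


def restrict_event_area(
    event: NetworkEvent,
    dff: DffMovie,
    fraction: float = 0.67,
    rounding: str = "printed",
) -> float:
    """Event area restricted to pixels reaching ``fraction`` of the peak.

    For every unique pixel of the event the within-event maximum dF/F0 is
    computed; pixels whose maximum reaches ``fraction * peak_dff`` count
    toward the area.  The result (um^2) is also stored on the event.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vt, vy, vx = event.voxels
    W = dff.dff.shape[2]
    pix = vy.astype(np.int64) * W + vx.astype(np.int64)
    uniq, inv = np.unique(pix, return_inverse=True)
    pixmax = np.full(uniq.size, -np.inf)
    np.maximum.at(pixmax, inv, dff.dff[vt, vy, vx].astype(np.float64))
    keep = pixmax >= fraction * event.peak_dff
    area = float(keep.sum()) * pixel_area_um2(event.pixel_size_um, rounding)
    event.restricted_area_um2 = area
    ys, xs = np.divmod(uniq[keep], W)
    event.restricted_footprint = np.stack([ys, xs], axis=1)
    return area


# --------------------------------------------------------------------------
# region assignment and frequency time courses
# --------------------------------------------------------------------------

def assign_regions(catalog: EventCatalog, regions: Sequence[RegionMask]) -> EventCatalog:
    """Assign each event to the region holding the majority of its footprint.

    Uses the restricted footprint when available, the full footprint
    otherwise; events whose best overlap is <= 50% stay unassigned.
    """
    for ev in catalog.events:
        fp = ev.restricted_footprint if ev.restricted_footprint is not None else ev.footprint_px
        if fp.size == 0:
            continue
        best_name, best_frac = None, 0.0
        for reg in regions:
            frac = float(reg.mask[fp[:, 0], fp[:, 1]].mean())
            if frac > best_frac:
                best_name, best_frac = reg.name, frac
        ev.region = best_name if best_frac > 0.5 else None
    return catalog


def event_frequency_timecourse(
    catalog: EventCatalog,
    bin_s: float = 300.0,
    region: str | None = None,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Events per ``bin_s`` converted to Hz, optionally for one region.

    Returns ``(bin_centers_s, frequency_hz)``.  Only full bins are used.
    """
    duration = duration_s if duration_s is not None else catalog.duration_s
    if bin_s > duration:
        raise ValueError(f"bin ({bin_s} s) longer than the recording ({duration} s)")
    n_bins = int(duration // bin_s)
    onsets = np.array(
        [ev.onset_s for ev in catalog.events if region is None or ev.region == region]
    )
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(onsets, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts / bin_s


def percent_change(baseline_mean: float, post_mean: float) -> float:
    """``100 * (post - baseline) / baseline``; rejects zero baseline."""
    if baseline_mean == 0:
        raise ValueError("baseline mean is zero; percent change undefined")
    return 100.0 * (post_mean - baseline_mean) / baseline_mean


# --------------------------------------------------------------------------
# awake-condition 1D trace peaks
# --------------------------------------------------------------------------

def detect_trace_peaks(
    trace: np.ndarray,
    frame_rate_hz: float,
    params: TracePeakParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass filter a dF/F0 trace and find prominent peaks.

    A 4th-order zero-phase Butterworth low-pass removes high-frequency
    movement artifacts, then peaks with the configured prominence and
    minimum height are returned as ``(times_s, amplitudes)``.
    """
    trace = np.asarray(trace, dtype=np.float64)
    nyq = frame_rate_hz / 2.0
    if params.lowpass_cutoff_hz >= nyq:
        raise ValueError(f"cutoff {params.lowpass_cutoff_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, params.lowpass_cutoff_hz / nyq, btype="low", output="sos")
    filt = signal.sosfiltfilt(sos, trace)
    peaks, props = signal.find_peaks(
        filt, height=params.min_peak_height, prominence=params.prominence
    )
    return peaks / frame_rate_hz, props["peak_heights"]
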