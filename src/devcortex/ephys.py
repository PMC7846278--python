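"""Patch-clamp feature extraction.

Covers the quantities used to characterize interneuron excitability and
synaptic drive in developing cortex:

* postsynaptic-current (PSC) detection with amplitude, 20-80% rise time
  (linear interpolation between fractional crossings) and rise rate
  (amplitude / rise time, pA/ms), binned into 50- or 90-s frequency
  timelines;
* single action-potential features — threshold (first point where dV/dt
  exceeds 20 mV/ms), overshoot (peak above 0 mV), amplitude (peak minus
  threshold), width at half amplitude, time from pulse onset to threshold,
  and maximal dV/dt;
* ramp excitability (-100 to +140 pA at 96 pA/s): instantaneous frequency
  (1 / mean ISI) per 175-ms bin against the mean injected current;
* a 45-s-binned membrane-potential timeline with spikes clipped out, and
  the series-resistance quality-control rule (fail above 30 MOhm or a
  change over 30%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PscEvent",
    "PscDetectionParams",
    "ApFeatures",
    "RampSpec",
    "RampBin",
    "RampResponse",
    "QcRecord",
    "detect_psc_events",
    "bin_frequency",
    "ap_features",
    "ramp_fi",
    "membrane_potential_timeline",
    "depolarization",
    "qc_series_resistance",
    "lif_rate_closed_form",
]


# --------------------------------------------------------------------------
# PSC detection
# --------------------------------------------------------------------------

@dataclass
class PscEvent:
    onset_s: float
    amplitude_pa: float
    rise_time_2080_ms: float

    @property
    def rise_rate_pa_per_ms(self) -> float:
        return self.amplitude_pa / self.rise_time_2080_ms


@dataclass
class PscDetectionParams:
    """Derivative-threshold detector settings.

    The trace is lightly smoothed, its derivative thresholded at
    ``deriv_thresh_sd`` robust SDs sustained for ``min_rise_ms``, and each
    candidate is kept only if its local-baseline amplitude exceeds
    ``amp_thresh_sd`` robust SDs of the trace.
    """

    smooth_ms: float = 0.3  # heavy smoothing for the detection derivative
    feature_smooth_ms: float = 0.05  # light smoothing for amplitude / rise measurement
    deriv_thresh_sd: float = 5.0
    amp_thresh_sd: float = 5.0
    min_rise_ms: float = 0.2
    baseline_ms: float = 2.0
    search_ms: float = 20.0
    min_interval_ms: float = 2.0
    polarity: int = 1  # +1 for outward/upward events


def _robust_sd(x: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """First interpolated crossing of ``level`` in the given direction."""
    if rising:
        idx = np.flatnonzero((y[:-1] < level) & (y[1:] >= level))
    else:
        idx = np.flatnonzero((y[:-1] >= level) & (y[1:] < level))
    if idx.size == 0:
        raise ValueError("no crossing found")
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def detect_psc_events(
    trace_pa: np.ndarray,
    sample_rate_hz: float,
    params: PscDetectionParams | None = None,
) -> list[PscEvent]:
    """Template-free PSC detection on a holding-current segment."""
    p = params or PscDetectionParams()
    fs = sample_rate_hz
    x = p.polarity * np.asarray(trace_pa, dtype=np.float64)
    sigma = max(p.smooth_ms / 1000.0 * fs, 1e-9)
    xs = ndimage.gaussian_filter1d(x, sigma)
    xf = ndimage.gaussian_filter1d(x, max(p.feature_smooth_ms / 1000.0 * fs, 1e-9))
    d = np.diff(xs)
    d_sd = max(_robust_sd(d), 1e-12)
    x_sd = max(_robust_sd(x), 1e-12)
    min_run = max(1, int(round(p.min_rise_ms / 1000.0 * fs)))
    hot = d > p.deriv_thresh_sd * d_sd
    # runs of sustained suprathreshold derivative
    lab, n_lab = ndimage.label(hot)
    events: list[PscEvent] = []
    last_onset = -np.inf
    n_base = max(1, int(round(p.baseline_ms / 1000.0 * fs)))
    n_search = max(2, int(round(p.search_ms / 1000.0 * fs)))
    t = np.arange(x.size) / fs
    for sl in ndimage.find_objects(lab):
        run = sl[0]
        if run.stop - run.start < min_run:
            continue
        i_on = run.start
        if (i_on - last_onset) / fs < p.min_interval_ms / 1000.0:
            continue
        base = float(np.median(xf[max(0, i_on - n_base) : i_on + 1]))
        seg = xf[i_on : min(x.size, i_on + n_search)]
        i_peak_rel = int(np.argmax(seg))
        amp = float(seg[i_peak_rel] - base)
        if amp < p.amp_thresh_sd * x_sd:
            continue
        rise_seg = seg[: i_peak_rel + 1]
        t_seg = t[i_on : i_on + i_peak_rel + 1]
        try:
            t20 = _interp_crossing(t_seg, rise_seg, base + 0.2 * amp, rising=True)
            t80 = _interp_crossing(t_seg, rise_seg, base + 0.8 * amp, rising=True)
        except ValueError:
            continue
        rise_ms = (t80 - t20) * 1000.0
        if rise_ms <= 0:
            continue
        events.append(PscEvent(onset_s=t[i_on], amplitude_pa=amp, rise_time_2080_ms=rise_ms))
        last_onset = i_on
    return events


def bin_frequency(
    events: list[PscEvent] | np.ndarray,
    duration_s: float,
    bin_s: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event frequency (Hz) in consecutive ``bin_s`` bins (full bins only)."""
    if bin_s > duration_s:
        raise ValueError("bin longer than the recorded segment")
    onsets = np.array([e.onset_s for e in events]) if events and isinstance(events[0], PscEvent) else np.asarray(events, dtype=float)
    n_bins = int(duration_s // bin_s)
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(onsets, bins=edges)
    return (edges[:-1] + edges[1:]) / 2.0, counts / bin_s


# --------------------------------------------------------------------------
# single-AP features
# --------------------------------------------------------------------------

@dataclass
class ApFeatures:
    threshold_mv: float
    peak_mv: float
    overshoot_mv: float
    amplitude_mv: float
    halfwidth_ms: float
    dtime_ms: float
    max_dvdt_mv_per_ms: float


def ap_features(
    trace_mv: np.ndarray,
    sample_rate_hz: float,
    pulse_onset_s: float,
    dvdt_threshold_mv_per_ms: float = 20.0,
) -> ApFeatures:
    """Features of the single AP following ``pulse_onset_s``."""
    v = np.asarray(trace_mv, dtype=np.float64)
    fs = sample_rate_hz
    t = np.arange(v.size) / fs
    dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
    i_start = int(round(pulse_onset_s * fs))
    cand = np.flatnonzero(dvdt[i_start:] >= dvdt_threshold_mv_per_ms)
    if cand.size == 0:
        raise ValueError("no AP detected: dV/dt never reaches the threshold criterion")
    i_thr = i_start + int(cand[0])
    threshold = float(v[i_thr])
    i_peak = i_thr + int(np.argmax(v[i_thr:]))
    peak = float(v[i_peak])
    amplitude = peak - threshold
    if amplitude <= 0:
        raise ValueError("no AP detected: non-positive amplitude above threshold")
    half = threshold + amplitude / 2.0
    t_up = _interp_crossing(t[i_thr : i_peak + 1], v[i_thr : i_peak + 1], half, rising=True)
    t_dn = _interp_crossing(t[i_peak:], v[i_peak:], half, rising=False)
    return ApFeatures(
        threshold_mv=threshold,
        peak_mv=peak,
        overshoot_mv=peak,  # amplitude of the AP above 0 mV
        amplitude_mv=amplitude,
        halfwidth_ms=(t_dn - t_up) * 1000.0,
        dtime_ms=(t[i_thr] - pulse_onset_s) * 1000.0,
        max_dvdt_mv_per_ms=float(dvdt[i_thr : i_peak + 1].max()),
    )


# --------------------------------------------------------------------------
# ramp excitability
# --------------------------------------------------------------------------

@dataclass
class RampSpec:
    onset_s: float = 0.0
    i_start_pa: float = -100.0
    i_end_pa: float = 140.0
    rate_pa_per_s: float = 96.0

    @property
    def duration_s(self) -> float:
        return (self.i_end_pa - self.i_start_pa) / self.rate_pa_per_s

    def current_at(self, t_s: float | np.ndarray) -> float | np.ndarray:
        return self.i_start_pa + self.rate_pa_per_s * (np.asarray(t_s) - self.onset_s)


@dataclass
class RampBin:
    t_start_s: float
    t_end_s: float
    mean_injected_pa: float
    mean_isi_s: float  # NaN when empty
    partial: bool = False

    @property
    def instantaneous_freq_hz(self) -> float:
        return 1.0 / self.mean_isi_s if np.isfinite(self.mean_isi_s) else np.nan


@dataclass
class RampResponse:
    bins: list[RampBin]
    spike_times_s: np.ndarray

    def populated(self) -> list[RampBin]:
        return [b for b in self.bins if np.isfinite(b.mean_isi_s)]


def spike_times_from_trace(
    trace_mv: np.ndarray, sample_rate_hz: float, threshold_mv: float = 0.0
) -> np.ndarray:
    """Interpolated upward crossings of ``threshold_mv``."""
    v = np.asarray(trace_mv, dtype=np.float64)
    up = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))
    frac = (threshold_mv - v[up]) / (v[up + 1] - v[up])
    return (up + frac) / sample_rate_hz


def ramp_fi(
    trace_mv: np.ndarray,
    sample_rate_hz: float,
    ramp: RampSpec,
    bin_ms: float = 175.0,
    spike_threshold_mv: float = 0.0,
) -> RampResponse:
    """Instantaneous frequency per ramp bin.

    ISIs are assigned to the bin containing the first spike of each pair;
    the frequency is the inverse of the bin's mean ISI; bins with no ISI
    are reported empty.  Full 175-ms bins tile the ramp; the remainder, if
    any, forms a final bin flagged ``partial``.
    """
    spikes = spike_times_from_trace(trace_mv, sample_rate_hz, spike_threshold_mv)
    spikes = spikes[(spikes >= ramp.onset_s) & (spikes <= ramp.onset_s + ramp.duration_s)]
    bw = bin_ms / 1000.0
    n_full = int(ramp.duration_s / bw + 1e-9)
    edges = [ramp.onset_s + i * bw for i in range(n_full + 1)]
    partial = []
    if ramp.onset_s + ramp.duration_s - edges[-1] > 1e-9:
        edges.append(ramp.onset_s + ramp.duration_s)
        partial = [True]
    flags = [False] * n_full + partial
    isis = np.diff(spikes)
    first = spikes[:-1]
    bins = []
    for (t0, t1), flag in zip(zip(edges[:-1], edges[1:]), flags):
        sel = (first >= t0) & (first < t1)
        mean_isi = float(isis[sel].mean()) if sel.any() else np.nan
        mean_i = float(ramp.current_at((t0 + t1) / 2.0))
        bins.append(RampBin(t0, t1, mean_i, mean_isi, partial=flag))
    return RampResponse(bins=bins, spike_times_s=spikes)


def lif_rate_closed_form(
    i_pa: float,
    g_l_ns: float,
    c_pf: float,
    v_rest_mv: float,
    v_th_mv: float,
    v_reset_mv: float,
    t_ref_ms: float = 0.0,
) -> float:
    """Stationary firing rate of a leaky integrate-and-fire neuron.

    ``f = 1 / (t_ref + tau_m ln((V_inf - V_reset) / (V_inf - V_th)))`` with
    ``V_inf = V_rest + I / g_L``; zero below rheobase.
    """
    v_inf = v_rest_mv + i_pa / g_l_ns
    if v_inf <= v_th_mv:
        return 0.0
    tau_s = c_pf / g_l_ns / 1000.0
    t_isi = t_ref_ms / 1000.0 + tau_s * math.log((v_inf - v_reset_mv) / (v_inf - v_th_mv))
    return 1.0 / t_isi


# --------------------------------------------------------------------------
# membrane-potential timeline and QC
# --------------------------------------------------------------------------

def membrane_potential_timeline(
    trace_mv: np.ndarray,
    sample_rate_hz: float,
    bin_s: float = 45.0,
    spike_threshold_mv: float = -20.0,
    clip_before_ms: float = 2.0,
    clip_after_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin median membrane potential with AP windows removed.

    Returns ``(bin_centers_s, vm_mv)``; bins fully occupied by clipped AP
    windows are NaN.
    """
    v = np.asarray(trace_mv, dtype=np.float64)
    fs = sample_rate_hz
    keep = np.ones(v.size, dtype=bool)
    crossings = np.flatnonzero((v[:-1] < spike_threshold_mv) & (v[1:] >= spike_threshold_mv))
    nb = int(round(clip_before_ms / 1000.0 * fs))
    na = int(round(clip_after_ms / 1000.0 * fs))
    for i in crossings:
        keep[max(0, i - nb) : min(v.size, i + na)] = False
    duration = v.size / fs
    if bin_s > duration:
        raise ValueError("bin longer than the recording")
    n_bins = int(duration // bin_s)
    w = int(round(bin_s * fs))
    centers = (np.arange(n_bins) + 0.5) * bin_s
    vm = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = keep[b * w : (b + 1) * w]
        seg = v[b * w : (b + 1) * w][sel]
        if seg.size:
            vm[b] = np.median(seg)
    return centers, vm


def depolarization(
    vm_bins_mv: np.ndarray,
    bin_centers_s: np.ndarray,
    application_time_s: float,
) -> float:
    """Peak post-application Vm minus the last baseline bin's Vm."""
    vm = np.asarray(vm_bins_mv, dtype=np.float64)
    t = np.asarray(bin_centers_s, dtype=np.float64)
    base = np.flatnonzero(t < application_time_s)
    post = np.flatnonzero(t >= application_time_s)
    if base.size == 0 or post.size == 0:
        raise ValueError("need at least one bin on each side of the application time")
    last_base = vm[base[np.isfinite(vm[base])][-1]]
    return float(np.nanmax(vm[post]) - last_base)


@dataclass
class QcRecord:
    series_resistance_mohm: np.ndarray

    def __post_init__(self) -> None:
        self.series_resistance_mohm = np.asarray(self.series_resistance_mohm, dtype=np.float64)
        if self.series_resistance_mohm.size < 2:
            raise ValueError("need at least two series-resistance measurements")


def qc_series_resistance(
    record: QcRecord,
    rs_limit_mohm: float = 30.0,
    max_rel_change: float = 0.30,
) -> bool:
    """True when the recording passes the series-resistance criteria.

    Fails when any Rs exceeds ``rs_limit_mohm`` or changes by more than
    ``max_rel_change`` relative to the first measurement.
    """
    rs = record.series_resistance_mohm
    if np.any(rs > rs_limit_mohm):
        return False
    if np.any(np.abs(rs - rs[0]) / rs[0] > max_rel_change):
        return False
    return True
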