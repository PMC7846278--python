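"""Seeded generators with analytic ground truth.

Three generators emulate the statistical structure the analysis modules
assume: wide-field movies with injected network events, two-photon ROI
populations with distance-structured pairwise correlations and a
subtractive post-application shift, and patch-clamp traces (biexponential
PSC trains, parametric action potentials).

All generators are deterministic given a spec and seed, drawing from named
RNG streams so fixtures stay stable when features are added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
from scipy import ndimage, optimize, signal

from .widefield import EventCatalog, FluorescenceMovie, NetworkEvent

__all__ = [
    "WidefieldSynthSpec",
    "RoiSynthSpec",
    "EphysSynthSpec",
    "RoiTraceSet",
    "RoiGroundTruth",
    "generate_widefield_events",
    "generate_widefield_movie",
    "generate_roi_population",
    "generate_psc_trace",
    "generate_ap_trace",
    "generate_ephys_traces",
    "biexp_waveform",
    "biexp_rise_time_2080",
]

F0_BASELINE_AU = 1000.0  # constant raw-fluorescence baseline, a.u.


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named RNG stream ``stream`` of a generator seeded with ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


# --------------------------------------------------------------------------
# wide-field movies
# --------------------------------------------------------------------------

@dataclass
class WidefieldSynthSpec:
    """Wide-field movie generator parameters.

    Defaults emulate the recording regime of the analyses: 20 Hz frame
    rate, 7.68 um pixels, region event rate 0.042 Hz, 30% peak dF/F0 events
    against noise whose SD stays at or below a third of the 12% detection
    threshold.
    """

    height_px: int = 48
    width_px: int = 48
    frame_rate_hz: float = 20.0
    pixel_size_um: float = 7.68
    duration_s: float = 600.0
    event_rate_hz: float = 0.042
    event_blob_sigma_um: float = 90.0
    event_peak_dff: float = 0.30
    event_rise_s: float = 0.05
    calcium_decay_s: float = 0.1
    noise_sd_dff: float = 0.03
    gt_threshold_dff: float = 0.12
    region_masks: dict[str, np.ndarray] | None = None
    application_time_s: float | None = None
    post_event_rate_factor: float = 1.0
    min_event_separation_s: float = 2.0
    event_times_s: dict[str, list[float]] | None = None  # fixed times per region (overrides the Poisson draw)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height_px, self.width_px) <= 0 or self.duration_s <= 0:
            raise ValueError("all dimensions must be positive")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame rate and pixel size must be positive")
        if self.noise_sd_dff < 0 or self.event_rate_hz < 0:
            raise ValueError("rates and noise must be non-negative")
        if self.noise_sd_dff > self.gt_threshold_dff / 3.0 + 1e-12:
            raise ValueError(
                "noise_sd_dff must not exceed a third of the detection threshold "
                f"({self.gt_threshold_dff / 3.0:.4f})"
            )
        if self.event_peak_dff <= self.gt_threshold_dff and self.event_rate_hz > 0:
            raise ValueError("event_peak_dff must exceed the ground-truth threshold")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def regions(self) -> dict[str, np.ndarray]:
        if self.region_masks is not None:
            for name, m in self.region_masks.items():
                if np.asarray(m).shape != (self.height_px, self.width_px):
                    raise ValueError(f"region mask {name!r} shape mismatch")
            return {k: np.asarray(v, dtype=bool) for k, v in self.region_masks.items()}
        return {"V1": np.ones((self.height_px, self.width_px), dtype=bool)}


def _event_frame_amplitudes(spec: WidefieldSynthSpec) -> np.ndarray:
    """Relative temporal kernel: linear rise then exponential decay."""
    n_rise = max(1, int(round(spec.event_rise_s * spec.frame_rate_hz)))
    rise = np.arange(1, n_rise + 1) / n_rise
    rel_thr = spec.gt_threshold_dff / spec.event_peak_dff
    n_decay = int(math.ceil(-math.log(max(rel_thr / 4.0, 1e-6)) * spec.calcium_decay_s * spec.frame_rate_hz))
    decay = np.exp(-np.arange(n_decay + 1) / (spec.calcium_decay_s * spec.frame_rate_hz))
    return np.concatenate([rise[:-1], decay])  # peak amplitude 1.0 once


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> list[float]:
    times, t = [], t0
    if rate_hz <= 0:
        return times
    while True:
        t += rng.exponential(1.0 / rate_hz)
        if t >= t1:
            return times
        times.append(t)


def _draw_events(spec: WidefieldSynthSpec) -> list[tuple[int, int, int, str]]:
    """Draw injected events as ``(injection_frame, cy_px, cx_px, region)``.

    Event times follow a per-region Poisson process thinned so successive
    events in one region are at least ``min_event_separation_s`` apart;
    when ``application_time_s`` is set the rate is multiplied by
    ``post_event_rate_factor`` afterwards.  Centers are uniform within the
    region mask eroded by the suprathreshold blob radius, so every event's
    full analytic voxel set lies inside the frame and voxel sets of
    distinct events are disjoint by construction.
    """
    rng_t = _rng(spec.seed, 0)
    rng_c = _rng(spec.seed, 1)
    sigma_px = spec.event_blob_sigma_um / spec.pixel_size_um
    rel_thr = spec.gt_threshold_dff / spec.event_peak_dff
    margin = int(math.ceil(sigma_px * math.sqrt(-2.0 * math.log(rel_thr)))) + 1
    drawn: list[tuple[int, int, int, str]] = []
    for name, mask in spec.regions().items():
        # frame edge counts as background so blobs stay fully inside
        padded = np.pad(mask, 1, constant_values=False)
        interior = ndimage.distance_transform_edt(padded)[1:-1, 1:-1] > margin
        iy, ix = np.nonzero(interior)
        if spec.event_rate_hz > 0 and iy.size == 0:
            raise ValueError(f"region {name!r} too small for the configured blob size")
        if spec.event_times_s is not None:
            raw = list(spec.event_times_s.get(name, []))
        elif spec.application_time_s is None:
            raw = _poisson_times(rng_t, spec.event_rate_hz, 0.0, spec.duration_s)
        else:
            raw = _poisson_times(rng_t, spec.event_rate_hz, 0.0, spec.application_time_s)
            raw += _poisson_times(
                rng_t,
                spec.event_rate_hz * spec.post_event_rate_factor,
                spec.application_time_s,
                spec.duration_s,
            )
        times: list[float] = []
        for t in raw:
            if not times or t - times[-1] >= spec.min_event_separation_s:
                times.append(t)
        for t_ev in times:
            k = rng_c.integers(0, iy.size)
            drawn.append((int(round(t_ev * spec.frame_rate_hz)), int(iy[k]), int(ix[k]), name))
    return drawn


def generate_widefield_events(spec: WidefieldSynthSpec) -> EventCatalog:
    """Ground-truth event catalog (analytic voxels, no movie rendering)."""
    sigma_px = spec.event_blob_sigma_um / spec.pixel_size_um
    amps = _event_frame_amplitudes(spec)
    T = spec.n_frames
    events: list[NetworkEvent] = []
    for onset, cy, cx, name in _draw_events(spec):
        vts, vys, vxs = [], [], []
        for i, a in enumerate(amps):
            fr = onset + i
            if fr >= T:
                break
            level = a * spec.event_peak_dff
            if level < spec.gt_threshold_dff:
                continue
            r = 0.0
            if level > spec.gt_threshold_dff:
                r = sigma_px * math.sqrt(2.0 * math.log(level / spec.gt_threshold_dff))
            rr = int(math.floor(r))
            yg, xg = np.mgrid[-rr : rr + 1, -rr : rr + 1]
            inside = yg * yg + xg * xg <= r * r
            vys.append((cy + yg[inside]).astype(np.intp))
            vxs.append((cx + xg[inside]).astype(np.intp))
            vts.append(np.full(int(inside.sum()), fr, dtype=np.intp))
        if not vts:
            continue
        vt, vy, vx = np.concatenate(vts), np.concatenate(vys), np.concatenate(vxs)
        events.append(
            NetworkEvent(
                voxels=(vt, vy, vx),
                onset_frame=int(vt.min()),
                offset_frame=int(vt.max()),
                peak_dff=float(spec.event_peak_dff),
                frame_rate_hz=spec.frame_rate_hz,
                pixel_size_um=spec.pixel_size_um,
                region=name,
            )
        )
    return EventCatalog(
        events=events,
        detection_params={"ground_truth": True, "threshold_dff": spec.gt_threshold_dff},
        frame_rate_hz=spec.frame_rate_hz,
        pixel_size_um=spec.pixel_size_um,
        duration_s=spec.duration_s,
    )


def generate_widefield_movie(
    spec: WidefieldSynthSpec,
) -> tuple[FluorescenceMovie, EventCatalog]:
    """Render a raw-intensity movie plus its ground-truth catalog.

    The raw movie is ``F0 * (1 + dff) + noise`` with a constant baseline of
    1000 a.u., which makes the dF/F0 round trip exact up to the moving
    average's response to the events themselves.
    """
    if spec.duration_s * spec.frame_rate_hz < 500:
        raise ValueError("duration shorter than the 500-frame baseline window")
    catalog = generate_widefield_events(spec)
    T, H, W = spec.n_frames, spec.height_px, spec.width_px
    dff = np.zeros((T, H, W), dtype=np.float32)
    amps = _event_frame_amplitudes(spec)
    sigma_px = spec.event_blob_sigma_um / spec.pixel_size_um
    r_render = int(math.ceil(sigma_px * math.sqrt(2.0 * math.log(spec.event_peak_dff / 0.001))))
    yg, xg = np.mgrid[-r_render : r_render + 1, -r_render : r_render + 1]
    blob = np.exp(-(yg * yg + xg * xg) / (2.0 * sigma_px * sigma_px)).astype(np.float32)

    for onset, cy, cx, _name in _draw_events(spec):
        y0, y1 = max(0, cy - r_render), min(H, cy + r_render + 1)
        x0, x1 = max(0, cx - r_render), min(W, cx + r_render + 1)
        patch = blob[
            y0 - (cy - r_render) : y1 - (cy - r_render),
            x0 - (cx - r_render) : x1 - (cx - r_render),
        ]
        for i, a in enumerate(amps):
            fr = onset + i
            if fr >= T:
                break
            dff[fr, y0:y1, x0:x1] += np.float32(a * spec.event_peak_dff) * patch

    frames = F0_BASELINE_AU * (1.0 + dff)
    if spec.noise_sd_dff > 0:
        rng_n = _rng(spec.seed, 2)
        noise = rng_n.standard_normal(frames.shape, dtype=np.float32)
        frames = frames + np.float32(spec.noise_sd_dff * F0_BASELINE_AU) * noise
        np.maximum(frames, 0.0, out=frames)
    movie = FluorescenceMovie(
        frames=frames, frame_rate_hz=spec.frame_rate_hz, pixel_size_um=spec.pixel_size_um
    )
    return movie, catalog


# --------------------------------------------------------------------------
# two-photon ROI populations
# --------------------------------------------------------------------------

@dataclass
class RoiSynthSpec:
    """ROI-population generator parameters.

    Cells are placed uniformly in the field of view.  Two event classes
    drive the traces: *local* network events (rate ``shared_event_rate_hz``)
    whose center recruits cells with probability
    ``exp(-d^2 / (2 * participation_corr_scale_um^2))``, giving
    distance-decaying pairwise correlations, and a low-amplitude *coherent
    background* calibrated so every pair's correlation carries an offset of
    ``sync_corr``.  After ``baseline_duration_s`` the coherent fraction of
    the background is reduced so each pair's correlation drops by
    ``subtractive_shift`` (floored at the local component), with per-cell
    rates and variances unchanged — a subtractive, not divisive, change.
    If ``subgroup_fraction > 0``, that fraction of cells instead switches
    to its own private coherent train post-application (rates unchanged),
    leaving a persistent re-structuring of the correlation matrix.
    """

    n_cells: int = 50
    fov_um: float = 300.0
    frame_rate_hz: float = 5.0
    baseline_duration_s: float = 2700.0
    post_duration_s: float = 2700.0
    shared_event_rate_hz: float = 0.15
    participation_corr_scale_um: float = 80.0
    transient_amplitude_dff: float = 0.3
    sync_corr: float = 0.2
    subtractive_shift: float = 0.1
    sync_amplitude_dff: float = 0.05
    subgroup_fraction: float = 0.0
    transient_decay_s: float = 1.0
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not 0.0 <= self.subtractive_shift <= 1.0:
            raise ValueError("subtractive_shift must be in [0, 1]")
        if not 0.0 <= self.sync_corr < 1.0:
            raise ValueError("sync_corr must be in [0, 1)")
        if not 4.0 <= self.frame_rate_hz <= 7.0:
            raise ValueError("frame_rate_hz must be in the 4-7 Hz acquisition range")

    @property
    def total_duration_s(self) -> float:
        return self.baseline_duration_s + self.post_duration_s


@dataclass
class RoiTraceSet:
    """Per-cell dF/F0 traces with positions and epoch bookkeeping."""

    cell_ids: np.ndarray
    positions_um: np.ndarray  # (N, 2)
    traces: np.ndarray  # (N, T)
    frame_rate_hz: float
    application_time_s: float
    baseline_span_s: float = 2700.0

    def __post_init__(self) -> None:
        if self.traces.shape[0] < 2:
            raise ValueError("need at least 2 cells")
        if self.traces.shape[0] != self.positions_um.shape[0]:
            raise ValueError("positions and traces misaligned")
        if not 0 < self.application_time_s <= self.traces.shape[1] / self.frame_rate_hz:
            raise ValueError("application_time_s outside the recording")

    @property
    def n_cells(self) -> int:
        return int(self.traces.shape[0])

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.frame_rate_hz


@dataclass
class RoiGroundTruth:
    """Analytic correlation structure and per-cell event times."""

    positions_um: np.ndarray
    local_event_times: list[np.ndarray]  # per cell, seconds
    target_baseline_corr: np.ndarray  # (N, N)
    target_post_corr: np.ndarray  # (N, N)
    p_bar: np.ndarray  # per-cell mean participation probability
    sync_rate_hz: float
    subgroup: np.ndarray  # indices of re-wired cells (may be empty)


def _participation_stats(spec: RoiSynthSpec, positions: np.ndarray, grid: int = 40):
    """Grid approximation of E_c[p_i] and E_c[min(p_i, p_j)] over uniform centers.

    Participation draws share one uniform per event (comonotone coupling),
    so the joint participation probability of a pair is ``min(p_i, p_j)``.
    """
    g = (np.arange(grid) + 0.5) / grid * spec.fov_um
    cx, cy = np.meshgrid(g, g, indexing="ij")
    centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
    d2 = ((positions[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    M = np.exp(-d2 / (2.0 * spec.participation_corr_scale_um ** 2))
    p_bar = M.mean(axis=1)
    emin = np.minimum(M[:, None, :], M[None, :, :]).mean(axis=2)
    return p_bar, emin


def generate_roi_population(spec: RoiSynthSpec) -> tuple[RoiTraceSet, RoiGroundTruth]:
    """Generate ROI traces plus analytic target correlation matrices."""
    rng_pos = _rng(spec.seed, 0)
    rng_loc = _rng(spec.seed, 1)
    rng_sync = _rng(spec.seed, 2)
    rng_noise = _rng(spec.seed, 3)

    N = spec.n_cells
    fs = spec.frame_rate_hz
    T = int(round(spec.total_duration_s * fs))
    t_app = spec.baseline_duration_s
    positions = rng_pos.uniform(0.0, spec.fov_um, size=(N, 2))

    # per-sample second moments of the convolved event trains
    rho = math.exp(-1.0 / (fs * spec.transient_decay_s))
    kappa = 1.0 / (1.0 - rho * rho)  # sum of squared kernel taps
    a_loc = kappa * spec.transient_amplitude_dff ** 2
    a_syn = kappa * spec.sync_amplitude_dff ** 2
    nu_l = spec.shared_event_rate_hz / fs
    p_bar, emin = _participation_stats(spec, positions)

    # calibrate the coherent-background rate so the mean pairwise sync
    # correlation equals sync_corr (fixed point in nu_g)
    pair_mask = ~np.eye(N, dtype=bool)
    nu_g = 0.0
    for _ in range(20):
        var = a_loc * nu_l * p_bar + a_syn * nu_g + spec.noise_sd ** 2
        inv_sqrt = 1.0 / np.sqrt(np.outer(var, var))
        mean_inv = inv_sqrt[pair_mask].mean()
        nu_g_new = spec.sync_corr / (a_syn * mean_inv) if spec.sync_corr > 0 else 0.0
        if abs(nu_g_new - nu_g) < 1e-15:
            nu_g = nu_g_new
            break
        nu_g = nu_g_new
    var = a_loc * nu_l * p_bar + a_syn * nu_g + spec.noise_sd ** 2
    inv_sqrt = 1.0 / np.sqrt(np.outer(var, var))
    sync_rate_hz = nu_g * fs

    corr_local = a_loc * nu_l * emin * inv_sqrt
    corr_sync = a_syn * nu_g * inv_sqrt
    coh_frac = 1.0 - min(spec.subtractive_shift / spec.sync_corr, 1.0) if spec.sync_corr > 0 else 0.0

    n_sub = int(round(spec.subgroup_fraction * N))
    subgroup = np.arange(n_sub) if n_sub > 0 else np.array([], dtype=int)
    sub_mask = np.zeros(N, dtype=bool)
    sub_mask[subgroup] = True

    target_base = corr_local + corr_sync
    target_post = corr_local + coh_frac * corr_sync
    if n_sub > 0:
        # re-wired cells keep full coherence within the subgroup but lose it
        # to the rest of the population
        within = np.outer(sub_mask, sub_mask)
        cross = np.outer(sub_mask, ~sub_mask) | np.outer(~sub_mask, sub_mask)
        target_post = corr_local + corr_sync
        target_post[cross] = corr_local[cross]
        target_post[within] = (corr_local + corr_sync)[within]
    np.fill_diagonal(target_base, 1.0)
    np.fill_diagonal(target_post, 1.0)

    # ---- build spike-like event trains per cell ----
    spikes = np.zeros((N, T), dtype=np.float64)
    local_times: list[list[float]] = [[] for _ in range(N)]

    # local network events, identical statistics in both epochs
    for t_ev in _poisson_times(rng_loc, spec.shared_event_rate_hz, 0.0, spec.total_duration_s):
        c = rng_loc.uniform(0.0, spec.fov_um, size=2)
        d2 = ((positions - c) ** 2).sum(1)
        p = np.exp(-d2 / (2.0 * spec.participation_corr_scale_um ** 2))
        part = rng_loc.random() < p  # one shared uniform: comonotone participation
        fr = int(t_ev * fs)
        spikes[part, fr] += spec.transient_amplitude_dff
        for i in np.nonzero(part)[0]:
            local_times[i].append(t_ev)

    # coherent background: baseline = one shared train for everyone
    if sync_rate_hz > 0:
        for t_ev in _poisson_times(rng_sync, sync_rate_hz, 0.0, t_app):
            spikes[:, int(t_ev * fs)] += spec.sync_amplitude_dff
        # post epoch: main coherent train at the reduced rate ...
        main = ~sub_mask
        for t_ev in _poisson_times(rng_sync, sync_rate_hz * coh_frac, t_app, spec.total_duration_s):
            spikes[main, int(t_ev * fs)] += spec.sync_amplitude_dff
        # ... plus per-cell private trains restoring each cell's rate
        priv_rate = sync_rate_hz * (1.0 - coh_frac)
        if priv_rate > 0:
            for i in np.nonzero(main)[0]:
                for t_ev in _poisson_times(rng_sync, priv_rate, t_app, spec.total_duration_s):
                    spikes[i, int(t_ev * fs)] += spec.sync_amplitude_dff
        # re-wired subgroup: its own full-rate coherent train post-application
        if n_sub > 0:
            for t_ev in _poisson_times(rng_sync, sync_rate_hz, t_app, spec.total_duration_s):
                spikes[subgroup, int(t_ev * fs)] += spec.sync_amplitude_dff

    traces = signal.lfilter([1.0], [1.0, -rho], spikes, axis=1)
    if spec.noise_sd > 0:
        traces = traces + spec.noise_sd * rng_noise.standard_normal(traces.shape)

    trace_set = RoiTraceSet(
        cell_ids=np.arange(N),
        positions_um=positions,
        traces=traces,
        frame_rate_hz=fs,
        application_time_s=t_app,
        baseline_span_s=min(2700.0, spec.baseline_duration_s),
    )
    gt = RoiGroundTruth(
        positions_um=positions,
        local_event_times=[np.array(ts) for ts in local_times],
        target_baseline_corr=target_base,
        target_post_corr=target_post,
        p_bar=p_bar,
        sync_rate_hz=sync_rate_hz,
        subgroup=subgroup,
    )
    return trace_set, gt


# --------------------------------------------------------------------------
# electrophysiology traces
# --------------------------------------------------------------------------

@dataclass
class EphysSynthSpec:
    """Patch-clamp trace generator parameters."""

    sample_rate_hz: float = 50_000.0
    duration_s: float = 10.0
    psc_rate_hz: float = 2.0
    psc_amplitude_pa: float = 30.0
    psc_rise_ms: float = 0.5
    psc_decay_ms: float = 5.0
    ap_overshoot_mv: float = 15.0
    ap_halfwidth_ms: float = 0.6
    ap_threshold_mv: float = -40.0
    ap_rest_mv: float = -60.0
    ap_pulse_onset_s: float = 0.01
    ap_dtime_ms: float = 3.0
    noise_sd_pa: float = 2.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psc_rise_ms >= self.psc_decay_ms:
            raise ValueError("PSC rise must be shorter than decay")
        if self.sample_rate_hz < 20_000.0:
            raise ValueError("sample_rate_hz must be >= 20 kHz")
        if self.ap_overshoot_mv <= 0 or self.ap_threshold_mv >= 0:
            raise ValueError("AP must overshoot 0 mV from a negative threshold")


def biexp_waveform(t_s: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak biexponential ``exp(-t/tau_d) - exp(-t/tau_r)``, t >= 0."""
    tr, td = rise_ms / 1000.0, decay_ms / 1000.0
    t = np.asarray(t_s, dtype=np.float64)
    w = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / td) - np.exp(-np.clip(t, 0, None) / tr), 0.0)
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return w / peak


def biexp_rise_time_2080(rise_ms: float, decay_ms: float) -> float:
    """Analytic 20-80% rise time (ms) of the unit-peak biexponential."""
    def level(frac: float) -> float:
        f = lambda t: biexp_waveform(np.array([t]), rise_ms, decay_ms)[0] - frac
        tr, td = rise_ms / 1000.0, decay_ms / 1000.0
        t_peak = tr * td / (td - tr) * math.log(td / tr)
        return optimize.brentq(f, 1e-12, t_peak)
    return (level(0.8) - level(0.2)) * 1000.0


def generate_psc_trace(spec: EphysSynthSpec) -> tuple[np.ndarray, list[dict]]:
    """Poisson train of biexponential PSCs plus noise.

    Returns ``(samples_pa, ground_truth)`` where each ground-truth entry
    holds the onset (s), amplitude (pA) and the analytic 20-80% rise time.
    """
    rng_t = _rng(spec.seed, 10)
    rng_n = _rng(spec.seed, 11)
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    trace = np.zeros(n)
    kern_len = int((spec.psc_decay_ms / 1000.0) * 8 * fs)
    t_kern = np.arange(kern_len) / fs
    kern = spec.psc_amplitude_pa * biexp_waveform(t_kern, spec.psc_rise_ms, spec.psc_decay_ms)
    rise_ms = biexp_rise_time_2080(spec.psc_rise_ms, spec.psc_decay_ms)
    gt = []
    for t_ev in _poisson_times(rng_t, spec.psc_rate_hz, 0.0, spec.duration_s):
        i0 = int(round(t_ev * fs))
        seg = min(kern_len, n - i0)
        if seg <= 0:
            continue
        trace[i0 : i0 + seg] += kern[:seg]
        gt.append(
            {
                "onset_s": i0 / fs,
                "amplitude_pa": spec.psc_amplitude_pa,
                "rise_time_2080_ms": rise_ms,
            }
        )
    if spec.noise_sd_pa > 0:
        trace += spec.noise_sd_pa * rng_n.standard_normal(n)
    return trace, gt


def generate_ap_trace(spec: EphysSynthSpec) -> tuple[np.ndarray, dict]:
    """Parametric single action potential with analytic features.

    A sub-threshold linear ramp starts at ``ap_pulse_onset_s`` and reaches
    the threshold after ``ap_dtime_ms``; the spike itself is a triangle
    whose rise slope is twice its fall slope, sized so the width at half
    amplitude equals ``ap_halfwidth_ms``.
    """
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    v = np.full(n, spec.ap_rest_mv)
    t_thr = spec.ap_pulse_onset_s + spec.ap_dtime_ms / 1000.0
    ramp = (t >= spec.ap_pulse_onset_s) & (t < t_thr)
    slope_ramp = (spec.ap_threshold_mv - spec.ap_rest_mv) / (spec.ap_dtime_ms / 1000.0)
    v[ramp] = spec.ap_rest_mv + slope_ramp * (t[ramp] - spec.ap_pulse_onset_s)

    amp = spec.ap_overshoot_mv - spec.ap_threshold_mv  # peak - threshold
    h = spec.ap_halfwidth_ms / 1000.0
    # half-width = (amp/2) * (1/r1 + 1/r2) with r1 = 2 r2
    r2 = 3.0 * amp / (4.0 * h)  # mV/s
    r1 = 2.0 * r2
    t_peak = t_thr + amp / r1
    t_end = t_peak + amp / r2
    up = (t >= t_thr) & (t < t_peak)
    down = (t >= t_peak) & (t < t_end)
    v[up] = spec.ap_threshold_mv + r1 * (t[up] - t_thr)
    v[down] = spec.ap_overshoot_mv - r2 * (t[down] - t_peak)
    v[t >= t_end] = spec.ap_rest_mv
    if spec.noise_sd_mv > 0:
        v = v + spec.noise_sd_mv * _rng(spec.seed, 12).standard_normal(n)
    gt = {
        "pulse_onset_s": spec.ap_pulse_onset_s,
        "threshold_mv": spec.ap_threshold_mv,
        "peak_mv": spec.ap_overshoot_mv,
        "overshoot_mv": spec.ap_overshoot_mv,
        "amplitude_mv": amp,
        "halfwidth_ms": spec.ap_halfwidth_ms,
        "dtime_ms": spec.ap_dtime_ms,
    }
    return v, gt


def generate_ephys_traces(spec: EphysSynthSpec, kind: str = "psc"):
    """Dispatch to the PSC (current) or AP (voltage) generator."""
    if kind == "psc":
        return generate_psc_trace(spec)
    if kind == "ap":
        return generate_ap_trace(spec)
    raise ValueError(f"unknown trace kind {kind!r}")
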