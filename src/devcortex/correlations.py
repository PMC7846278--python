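"""Two-photon population analysis: windowed correlations and the MSD statistic.

Pairwise Pearson correlations are computed directly on continuous dF/F0
traces, in sliding 7-minute windows.  Three derived analyses quantify how a
perturbation (e.g. a neuromodulator application) reshapes the population:

* distance dependence — per-pair correlation change (absolute and percent)
  against interneuronal distance, with a per-dataset Pearson r between
  distance and percent change;
* the correlation-matrix mean squared distance (MSD),
  ``MSD(t) = sum_ij (c_ij^t - c_ij^BL)^2`` against the matrix of the full
  45-minute baseline, linearly detrended on the baseline and z-scored by
  the baseline mean and SD;
* a subtractive-vs-divisive classifier comparing the shift model
  ``post = base - c`` and the scaling model ``post = a * base`` by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist

from .synthetic import RoiTraceSet

__all__ = [
    "EventRaster",
    "CorrelationWindowSeries",
    "DistanceCorrelationResult",
    "MsdSeries",
    "ModulationFit",
    "detect_roi_events",
    "noise_sd_estimate",
    "windowed_correlations",
    "epoch_correlation",
    "distance_dependence",
    "correlation_msd",
    "classify_modulation",
    "sem",
]


# --------------------------------------------------------------------------
# ROI event detection
# --------------------------------------------------------------------------

@dataclass
class EventRaster:
    """Per-cell event onsets and amplitudes from thresholded dF/F0 traces."""

    event_times_s: list[np.ndarray]
    event_amplitudes: list[np.ndarray]
    thresholds: np.ndarray
    detection_threshold_sd: float = 2.0

    @property
    def n_cells(self) -> int:
        return len(self.event_times_s)

    def rate_hz(self, duration_s: float) -> np.ndarray:
        return np.array([t.size for t in self.event_times_s]) / duration_s


def noise_sd_estimate(trace: np.ndarray) -> float:
    """Robust noise SD: ``1.4826 * MAD(diff(trace)) / sqrt(2)``.

    The first difference suppresses slow transients, so the estimate
    approximates the SD of the signal in the absence of events without
    manual annotation.
    """
    d = np.diff(np.asarray(trace, dtype=np.float64))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_roi_events(
    traces: RoiTraceSet, k_sd: float = 2.0, min_duration_frames: int = 3
) -> EventRaster:
    """Upward threshold crossings at ``k_sd`` times the per-cell noise SD.

    A crossing opens an event only if the trace stays suprathreshold for
    ``min_duration_frames`` (calcium transients outlast single-sample noise
    excursions); the trace must then fall back below half the threshold
    before another onset is accepted (hysteresis), which keeps noise riding
    on a decaying transient from splitting it into several events.
    Thresholds are per cell and constant across the recording.
    """
    if not np.all(np.isfinite(traces.traces)):
        raise ValueError("traces contain non-finite values")
    fs = traces.frame_rate_hz
    times, amps, thresholds = [], [], []
    for x in traces.traces:
        sd = noise_sd_estimate(x)
        if sd == 0:
            raise ValueError("constant trace: noise SD is zero, threshold undefined")
        thr = k_sd * sd
        thresholds.append(thr)
        above = x >= thr
        onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        release = thr / 2.0
        kept, kept_amp = [], []
        last_end = -1
        for i in onsets:
            if i <= last_end:
                continue
            if not np.all(x[i : i + min_duration_frames] >= thr):
                continue
            j = i
            while j < x.size and x[j] >= release:
                j += 1
            kept.append(i)
            kept_amp.append(float(x[i:j].max()))
            last_end = j
        times.append(np.array(kept) / fs)
        amps.append(np.array(kept_amp))
    return EventRaster(
        event_times_s=times,
        event_amplitudes=amps,
        thresholds=np.array(thresholds),
        detection_threshold_sd=k_sd,
    )


# --------------------------------------------------------------------------
# windowed correlation matrices
# --------------------------------------------------------------------------

@dataclass
class CorrelationWindowSeries:
    window_centers_s: np.ndarray
    window_length_s: float
    matrices: np.ndarray  # (n_windows, N, N); NaN marks excluded cells
    mean_pairwise: np.ndarray
    n_excluded_cells: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.matrices.shape[0])

    @property
    def n_cells(self) -> int:
        return int(self.matrices.shape[1])


def _corr_matrix(sub: np.ndarray) -> tuple[np.ndarray, int]:
    sd = sub.std(axis=1)
    valid = sd > 0
    n = sub.shape[0]
    c = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        c_valid = np.corrcoef(sub[valid])
        c[np.ix_(valid, valid)] = c_valid
    c[np.arange(n), np.arange(n)] = np.where(valid, 1.0, np.nan)
    return c, int((~valid).sum())


def windowed_correlations(
    traces: RoiTraceSet,
    window_s: float = 420.0,
    step_s: float = 60.0,
) -> CorrelationWindowSeries:
    """Sliding-window Pearson correlation matrices of raw dF/F0 traces.

    Windows of ``window_s`` slide in steps of ``step_s``; each matrix holds
    all pairwise coefficients; ``mean_pairwise`` averages over the
    ``N (N - 1) / 2`` unordered pairs.  Cells with zero variance inside a
    window are excluded from that window's matrix and mean, with a count.
    """
    fs = traces.frame_rate_hz
    dur = traces.duration_s
    if dur < window_s:
        raise ValueError("recording shorter than the correlation window")
    w = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    starts = np.arange(0, traces.traces.shape[1] - w + 1, step)
    n = traces.n_cells
    mats = np.empty((starts.size, n, n))
    means = np.empty(starts.size)
    excl = np.empty(starts.size, dtype=int)
    iu = np.triu_indices(n, k=1)
    for m, s in enumerate(starts):
        c, n_ex = _corr_matrix(traces.traces[:, s : s + w])
        mats[m] = c
        means[m] = np.nanmean(c[iu])
        excl[m] = n_ex
    centers = (starts + w / 2.0) / fs
    return CorrelationWindowSeries(
        window_centers_s=centers,
        window_length_s=window_s,
        matrices=mats,
        mean_pairwise=means,
        n_excluded_cells=excl,
    )


def epoch_correlation(traces: RoiTraceSet, t0_s: float, t1_s: float) -> np.ndarray:
    """Pearson correlation matrix over one contiguous epoch."""
    fs = traces.frame_rate_hz
    i0, i1 = int(round(t0_s * fs)), int(round(t1_s * fs))
    if i1 - i0 < 2:
        raise ValueError("epoch too short")
    c, _ = _corr_matrix(traces.traces[:, i0:i1])
    return c


# --------------------------------------------------------------------------
# distance dependence of the correlation change
# --------------------------------------------------------------------------

@dataclass
class DistanceCorrelationResult:
    pair_distances_um: np.ndarray
    baseline_corr: np.ndarray
    post_corr: np.ndarray
    delta_corr: np.ndarray
    pct_change: np.ndarray  # NaN where |baseline| < eps
    n_pairs_excluded: int
    delta_fit: dict
    pct_fit: dict
    pearson_r_distance_vs_pct_change: float
    r_undefined: bool = False


def _windows_in_epoch(series: CorrelationWindowSeries, t0: float, t1: float) -> np.ndarray:
    half = series.window_length_s / 2.0
    c = series.window_centers_s
    return np.flatnonzero((c - half >= t0 - 1e-9) & (c + half <= t1 + 1e-9))


def distance_dependence(
    series: CorrelationWindowSeries,
    positions_um: np.ndarray,
    epochs: tuple[tuple[float, float], tuple[float, float]],
    eps: float = 0.01,
) -> DistanceCorrelationResult:
    """Per-pair correlation change against interneuronal distance.

    Baseline and post correlations are averages over the windows fully
    contained in each epoch; ``pct_change = 100 * delta / baseline`` is
    reported only for pairs with ``|baseline| >= eps``.  OLS lines of delta
    and percent change versus distance are fitted, and the per-dataset
    Pearson r between distance and percent change is returned.
    """
    (b0, b1), (p0, p1) = epochs
    wb = _windows_in_epoch(series, b0, b1)
    wp = _windows_in_epoch(series, p0, p1)
    if wb.size == 0:
        raise ValueError("baseline epoch contains no complete window")
    if wp.size == 0:
        raise ValueError("post epoch contains no complete window")
    iu = np.triu_indices(series.n_cells, k=1)
    base = np.nanmean(series.matrices[wb], axis=0)[iu]
    post = np.nanmean(series.matrices[wp], axis=0)[iu]
    dist = pdist(np.asarray(positions_um, dtype=np.float64))
    delta = post - base
    ok = np.abs(base) >= eps
    pct = np.full(delta.shape, np.nan)
    pct[ok] = 100.0 * delta[ok] / base[ok]

    def _fit(y: np.ndarray) -> dict:
        m = np.isfinite(y)
        if m.sum() < 3 or np.ptp(dist[m]) == 0:
            return {"slope": 0.0, "intercept": float(np.nanmean(y)) if m.any() else 0.0, "p": np.nan}
        res = stats.linregress(dist[m], y[m])
        return {"slope": float(res.slope), "intercept": float(res.intercept), "p": float(res.pvalue)}

    m = np.isfinite(pct)
    r_undef = m.sum() < 3 or np.allclose(pct[m], pct[m][0]) or np.ptp(dist[m]) == 0
    r = 0.0 if r_undef else float(stats.pearsonr(dist[m], pct[m])[0])
    return DistanceCorrelationResult(
        pair_distances_um=dist,
        baseline_corr=base,
        post_corr=post,
        delta_corr=delta,
        pct_change=pct,
        n_pairs_excluded=int((~ok).sum()),
        delta_fit=_fit(delta),
        pct_fit=_fit(pct),
        pearson_r_distance_vs_pct_change=r,
        r_undefined=r_undef,
    )


# --------------------------------------------------------------------------
# correlation-matrix MSD
# --------------------------------------------------------------------------

@dataclass
class MsdSeries:
    times_s: np.ndarray
    msd_raw: np.ndarray
    msd_detrended: np.ndarray
    msd_normalized: np.ndarray
    baseline_matrix: np.ndarray
    baseline_window_idx: np.ndarray
    detrended_flag: bool
    degenerate_flag: bool = False


def matrix_msd(c_t: np.ndarray, c_bl: np.ndarray, entries: str = "all") -> float:
    """Squared distance between two correlation matrices.

    ``entries="all"`` sums over all N^2 entries (symmetric off-diagonal
    differences count twice, the diagonal contributes zero);
    ``entries="upper"`` sums over i < j only, which is exactly half.
    """
    d = np.asarray(c_t, dtype=np.float64) - np.asarray(c_bl, dtype=np.float64)
    d = np.nan_to_num(d)
    if entries == "all":
        return float(np.sum(d * d))
    if entries == "upper":
        iu = np.triu_indices(d.shape[0], k=1)
        return float(np.sum(d[iu] ** 2))
    raise ValueError(f"unknown entries mode {entries!r}")


def correlation_msd(
    traces: RoiTraceSet,
    series: CorrelationWindowSeries,
    baseline_span_s: float | None = None,
    entries: str = "all",
) -> MsdSeries:
    """MSD between each windowed matrix and the full-baseline matrix.

    The baseline matrix is computed over the whole baseline span (default
    ``traces.baseline_span_s``, 45 min).  A linear trend fitted on the
    baseline-epoch MSD values is subtracted from all time points, and the
    detrended series is z-scored by the baseline mean and SD.  With fewer
    than 3 baseline windows detrending is skipped (flagged); a degenerate
    baseline SD of 0 yields an all-zero normalized series (flagged).
    """
    span = baseline_span_s if baseline_span_s is not None else traces.baseline_span_s
    if span < series.window_length_s:
        raise ValueError("baseline span shorter than the correlation window")
    c_bl = epoch_correlation(traces, 0.0, span)
    msd_raw = np.array([matrix_msd(series.matrices[i], c_bl, entries) for i in range(series.n_windows)])
    wb = _windows_in_epoch(series, 0.0, span)
    times = series.window_centers_s

    detrended_flag = wb.size >= 3
    if detrended_flag:
        slope, intercept = np.polyfit(times[wb], msd_raw[wb], 1)
        msd_det = msd_raw - (slope * times + intercept)
    else:
        msd_det = msd_raw.copy()

    mu = msd_det[wb].mean() if wb.size else 0.0
    sd = msd_det[wb].std(ddof=1) if wb.size > 1 else 0.0
    degenerate = sd == 0.0
    msd_norm = np.zeros_like(msd_det) if degenerate else (msd_det - mu) / sd
    return MsdSeries(
        times_s=times,
        msd_raw=msd_raw,
        msd_detrended=msd_det,
        msd_normalized=msd_norm,
        baseline_matrix=c_bl,
        baseline_window_idx=wb,
        detrended_flag=detrended_flag,
        degenerate_flag=degenerate,
    )


# --------------------------------------------------------------------------
# subtractive vs divisive modulation
# --------------------------------------------------------------------------

@dataclass
class ModulationFit:
    label: str  # subtractive | divisive | mixed | indeterminate
    shift_c: float
    scale_a: float
    rss_subtractive: float
    rss_divisive: float
    aic_subtractive: float
    aic_divisive: float


def classify_modulation(
    baseline_corr: np.ndarray,
    post_corr: np.ndarray,
    aic_margin: float = 2.0,
) -> ModulationFit:
    """Compare shift (``post = base - c``) and scaling (``post = a base``).

    Both one-parameter models are fitted by least squares and compared by
    AIC; labels: the better model when the AIC difference exceeds
    ``aic_margin``, ``mixed`` otherwise, ``indeterminate`` when the
    baseline correlations are (numerically) all equal.
    """
    base = np.asarray(baseline_corr, dtype=np.float64)
    post = np.asarray(post_corr, dtype=np.float64)
    m = np.isfinite(base) & np.isfinite(post)
    base, post = base[m], post[m]
    n = base.size
    if n < 10:
        raise ValueError("need at least 10 pairs to classify modulation")
    c = float(np.mean(base - post))
    rss_sub = float(np.sum((post - (base - c)) ** 2))
    denom = float(np.sum(base * base))
    if np.ptp(base) < 1e-12 or denom == 0:
        return ModulationFit("indeterminate", c, np.nan, rss_sub, np.nan, np.nan, np.nan)
    a = float(np.sum(base * post) / denom)
    rss_div = float(np.sum((post - a * base) ** 2))
    tiny = 1e-300
    aic_sub = n * np.log(max(rss_sub, tiny) / n) + 2.0
    aic_div = n * np.log(max(rss_div, tiny) / n) + 2.0
    if abs(aic_sub - aic_div) < aic_margin:
        label = "mixed"
    else:
        label = "subtractive" if aic_sub < aic_div else "divisive"
    return ModulationFit(label, c, a, rss_sub, rss_div, float(aic_sub), float(aic_div))


def sem(values: np.ndarray, convention: str = "standard") -> float:
    """Across-animal dispersion: ``sd/sqrt(N)`` or the printed ``sd/N``."""
    v = np.asarray(values, dtype=np.float64)
    sd = v.std(ddof=1)
    if convention == "standard":
        return float(sd / np.sqrt(v.size))
    if convention == "printed":
        return float(sd / v.size)
    raise ValueError(f"unknown SEM convention {convention!r}")
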