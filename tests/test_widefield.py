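"""Wide-field network-event detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import devcortex as dc
from devcortex.widefield import DffMovie

from conftest import flood_fill_components


def make_dff(arr, frame_rate=20.0, pixel=7.68):
    return DffMovie(np.asarray(arr, dtype=np.float32), frame_rate, pixel)


# --------------------------------------------------------------------------
# worked-example constants
# --------------------------------------------------------------------------

def test_pixel_area_printed_and_exact_modes():
    assert dc.pixel_area_um2(7.68, "printed") == 59.0
    assert dc.pixel_area_um2(7.68, "exact") == pytest.approx(58.9824)
    with pytest.raises(ValueError):
        dc.pixel_area_um2(7.68, "bogus")


def test_min_mean_frame_area_reproduces_printed_value():
    # 300 voxels over a 1-s event at 20 Hz -> 15 px/frame x 59 um^2 = 885 um^2
    assert dc.min_mean_frame_area_um2() == 885.0


# --------------------------------------------------------------------------
# dF/F0
# --------------------------------------------------------------------------

def test_constant_movie_gives_zero_dff():
    movie = dc.FluorescenceMovie(np.full((60, 4, 4), 1000.0))
    dff = dc.compute_dff(movie, window=50)
    assert np.allclose(dff.dff, 0.0)


def test_single_frame_pulse_matches_bruteforce_moving_average():
    T, w = 200, 100
    f = np.full((T, 1, 1), 1000.0)
    f[80, 0, 0] = 1120.0
    dff = dc.compute_dff(dc.FluorescenceMovie(f), window=w)
    series = f[:, 0, 0]
    half = w // 2
    expected = np.empty(T)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        f0 = series[lo:hi].mean()
        expected[t] = (series[t] - f0) / f0
    assert np.allclose(dff.dff[:, 0, 0], expected, atol=1e-6)
    # ~0.12 minus the pulse's own contribution to F0
    assert 0.10 < dff.dff[80, 0, 0] < 0.12


def test_dff_rejects_short_movies_and_bad_f0():
    with pytest.raises(ValueError, match="shorter"):
        dc.compute_dff(dc.FluorescenceMovie(np.full((10, 2, 2), 1000.0)), window=50)
    f = np.full((60, 2, 2), 1000.0)
    f[:, 1, 0] = 0.0
    with pytest.raises(ValueError, match=r"y=1, x=0"):
        dc.compute_dff(dc.FluorescenceMovie(f), window=50)


def test_roundtrip_recovers_generator_peak_dff(small_widefield):
    _, movie, catalog = small_widefield
    dff = dc.compute_dff(movie)
    det = dc.detect_network_events(dff)
    assert len(det) == len(catalog)
    for ev in det:
        assert ev.peak_dff == pytest.approx(0.30, rel=0.01)


# --------------------------------------------------------------------------
# event detection
# --------------------------------------------------------------------------

def test_component_size_vs_min_event_size_threshold():
    arr = np.zeros((10, 12, 12))
    arr[2:6, 2:12, 2:12] = 0.2  # 4 x 10 x 10 = 400 voxels
    cat = dc.detect_network_events(make_dff(arr), min_event_size=300)
    assert len(cat) == 1 and cat.events[0].n_voxels == 400
    assert len(dc.detect_network_events(make_dff(arr), min_event_size=500)) == 0


def test_two_separated_blobs_are_two_events():
    arr = np.zeros((12, 10, 10))
    arr[1:3, 1:4, 1:4] = 0.3
    arr[6:8, 6:9, 6:9] = 0.3
    cat = dc.detect_network_events(make_dff(arr), min_event_size=5)
    assert len(cat) == 2
    oracle = flood_fill_components(arr >= 0.12, "full")
    assert {frozenset(c) for c in oracle} == {frozenset(e.voxel_set()) for e in cat}


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from(["full", "face"]))
def test_labeling_matches_flood_fill_oracle(seed, connectivity):
    rng = np.random.default_rng(seed)
    mask = rng.random((8, 8, 8)) < 0.25
    arr = np.where(mask, 0.2, 0.0)
    cat = dc.detect_network_events(make_dff(arr), min_event_size=1, connectivity=connectivity)
    oracle = flood_fill_components(mask, connectivity)
    assert {frozenset(c) for c in oracle} == {frozenset(e.voxel_set()) for e in cat}


def test_event_count_monotone_in_threshold_and_size(small_widefield):
    # monotonicity in threshold holds for blob-shaped events (level sets
    # shrink without fragmenting); min-size monotonicity holds always
    _, movie, _ = small_widefield
    dff = dc.compute_dff(movie)
    counts_thr = [len(dc.detect_network_events(dff, threshold=t, min_event_size=5)) for t in (0.12, 0.16, 0.2, 0.25, 0.31)]
    assert counts_thr == sorted(counts_thr, reverse=True)
    assert counts_thr[-1] == 0
    rng = np.random.default_rng(3)
    noisy = make_dff(rng.random((20, 15, 15)) * 0.3)
    counts_sz = [len(dc.detect_network_events(noisy, threshold=0.12, min_event_size=s)) for s in (1, 5, 20, 100)]
    assert counts_sz == sorted(counts_sz, reverse=True)


def test_voxel_conservation():
    rng = np.random.default_rng(5)
    arr = rng.random((15, 10, 10)) * 0.3
    dff = make_dff(arr)
    n_supra = int((arr >= 0.12).sum())
    cat_all = dc.detect_network_events(dff, min_event_size=1)
    assert sum(e.n_voxels for e in cat_all) == n_supra
    cat_big = dc.detect_network_events(dff, min_event_size=10)
    assert sum(e.n_voxels for e in cat_big) <= n_supra


def test_detection_count_robust_to_min_size(small_widefield):
    # injected events carry far more voxels than any of these criteria
    _, movie, catalog = small_widefield
    assert min(e.n_voxels for e in catalog) > 900
    dff = dc.compute_dff(movie)
    counts = {s: len(dc.detect_network_events(dff, min_event_size=s)) for s in (200, 300, 800)}
    assert set(counts.values()) == {len(catalog)}


# --------------------------------------------------------------------------
# restricted area
# --------------------------------------------------------------------------

def test_restricted_area_uniform_event_counts_all_pixels():
    arr = np.zeros((6, 12, 12))
    arr[2, 1:11, 1:11] = 0.2  # uniform 100-px event
    cat = dc.detect_network_events(make_dff(arr), min_event_size=10)
    area = dc.restrict_event_area(cat.events[0], make_dff(arr))
    assert area == 100 * 59.0


def test_restricted_area_peak_pixel_only():
    arr = np.zeros((6, 9, 9))
    arr[2, 2:7, 2:7] = 0.15  # 0.5 x peak
    arr[2, 4, 4] = 0.30
    cat = dc.detect_network_events(make_dff(arr), min_event_size=5)
    area = dc.restrict_event_area(cat.events[0], make_dff(arr))
    assert area == 59.0


def test_restricted_area_gaussian_blob_matches_analytic_radius():
    sigma_px = 6.0
    yy, xx = np.mgrid[0:41, 0:41] - 20.0
    blob = 0.3 * np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    arr = np.zeros((5, 41, 41))
    arr[2] = blob
    dff = make_dff(arr)
    cat = dc.detect_network_events(dff, min_event_size=10)
    area = dc.restrict_event_area(cat.events[0], dff, rounding="exact")
    r67 = sigma_px * np.sqrt(-2 * np.log(0.67))
    expected = int(((yy**2 + xx**2) <= r67**2).sum())
    assert area == pytest.approx(expected * 7.68**2)


def test_restricted_area_validates_fraction_and_is_subset(small_widefield):
    _, movie, _ = small_widefield
    dff = dc.compute_dff(movie)
    cat = dc.detect_network_events(dff)
    for ev in cat:
        with pytest.raises(ValueError):
            dc.restrict_event_area(ev, dff, fraction=1.5)
        dc.restrict_event_area(ev, dff)
        fp = {tuple(p) for p in ev.footprint_px}
        rfp = {tuple(p) for p in ev.restricted_footprint}
        assert rfp <= fp
        assert ev.restricted_area_um2 <= len(fp) * 59.0


# --------------------------------------------------------------------------
# frequency time courses and percent change
# --------------------------------------------------------------------------

def _toy_catalog(onsets_s, duration_s, frame_rate=20.0):
    events = [
        dc.NetworkEvent(
            voxels=(np.array([int(t * frame_rate)]), np.array([0]), np.array([0])),
            onset_frame=int(t * frame_rate),
            offset_frame=int(t * frame_rate),
            peak_dff=0.3,
            frame_rate_hz=frame_rate,
            pixel_size_um=7.68,
        )
        for t in onsets_s
    ]
    return dc.EventCatalog(events=events, frame_rate_hz=frame_rate, duration_s=duration_s)


def test_frequency_timecourse_uniform_events():
    cat = _toy_catalog(np.arange(12) * 50.0 + 10.0, duration_s=600.0)
    centers, freq = dc.event_frequency_timecourse(cat, bin_s=300.0)
    assert np.allclose(freq, [0.02, 0.02])
    assert np.allclose(centers, [150.0, 450.0])


def test_frequency_timecourse_empty_catalog_and_bad_bin():
    cat = _toy_catalog([], duration_s=600.0)
    _, freq = dc.event_frequency_timecourse(cat, bin_s=300.0)
    assert np.allclose(freq, 0.0)
    with pytest.raises(ValueError):
        dc.event_frequency_timecourse(cat, bin_s=1200.0)


def test_frequency_timecourse_matches_ground_truth_counts():
    h, w = 64, 96
    masks = {
        "V1": np.zeros((h, w), bool),
        "S1": np.zeros((h, w), bool),
    }
    masks["V1"][:, :48] = True
    masks["S1"][:, 48:] = True
    spec = dc.WidefieldSynthSpec(
        height_px=h, width_px=w, duration_s=600.0, region_masks=masks, seed=2
    )
    catalog = dc.generate_widefield_events(spec)
    for name in masks:
        n_direct = sum(1 for e in catalog if e.region == name)
        _, freq = dc.event_frequency_timecourse(catalog, bin_s=300.0, region=name)
        assert round(freq.sum() * 300.0) == n_direct


def test_percent_change():
    assert dc.percent_change(0.042, 0.042) == 0.0
    assert dc.percent_change(0.040, 0.020) == -50.0
    with pytest.raises(ValueError):
        dc.percent_change(0.0, 0.1)


# --------------------------------------------------------------------------
# awake 1D-trace peaks
# --------------------------------------------------------------------------

def test_trace_peaks_clean_and_artifact_contaminated():
    fs = 20.0
    t = np.arange(0, 120.0, 1 / fs)
    trace = np.zeros_like(t)
    peak_times = [10.0, 30.0, 55.0, 80.0, 105.0]
    for pt in peak_times:
        trace += 0.3 * np.exp(-((t - pt) ** 2) / (2 * 0.5**2))
    params = dc.TracePeakParams(lowpass_cutoff_hz=2.0, prominence=0.1, min_peak_height=0.1)
    times, amps = dc.detect_trace_peaks(trace, fs, params)
    assert len(times) == 5
    assert np.allclose(times, peak_times, atol=0.2)
    # a 7 Hz artifact above the cutoff is attenuated away
    noisy = trace + 0.08 * np.sin(2 * np.pi * 7.0 * t)
    times2, _ = dc.detect_trace_peaks(noisy, fs, params)
    assert len(times2) == 5


def test_trace_peaks_flat_trace_and_bad_cutoff():
    params = dc.TracePeakParams(lowpass_cutoff_hz=2.0, prominence=0.05, min_peak_height=0.05)
    times, _ = dc.detect_trace_peaks(np.zeros(500), 20.0, params)
    assert len(times) == 0
    with pytest.raises(ValueError):
        dc.detect_trace_peaks(np.zeros(500), 20.0, dc.TracePeakParams(lowpass_cutoff_hz=11.0))
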