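"""Windowed correlations, distance dependence, MSD, modulation classifier."""

import numpy as np
import pytest

import devcortex as dc
from devcortex import correlations as co
from devcortex.synthetic import RoiTraceSet


def make_traces(arr, fs=5.0, t_app=None, positions=None):
    arr = np.asarray(arr, dtype=np.float64)
    n = arr.shape[0]
    if positions is None:
        rng = np.random.default_rng(0)
        positions = rng.uniform(0, 300, (n, 2))
    if t_app is None:
        t_app = arr.shape[1] / fs / 2
    return RoiTraceSet(
        cell_ids=np.arange(n),
        positions_um=positions,
        traces=arr,
        frame_rate_hz=fs,
        application_time_s=t_app,
        baseline_span_s=t_app,
    )


# --------------------------------------------------------------------------
# ROI event detection
# --------------------------------------------------------------------------

def test_transients_counted_once_each():
    fs = 5.0
    t = np.arange(0, 600, 1 / fs)
    trace = np.zeros_like(t)
    for pt in (50, 180, 320, 500):
        trace += 0.5 * np.exp(-np.clip(t - pt, 0, None) / 1.0) * (t >= pt)
    trace += 0.01 * np.random.default_rng(1).standard_normal(t.size)
    raster = co.detect_roi_events(make_traces(trace[None, :].repeat(2, axis=0)))
    assert all(times.size == 4 for times in raster.event_times_s)


def test_gaussian_noise_false_positives_bounded():
    # at 5 robust SDs the expected count of upward crossings in 1000
    # samples is far below 1 (Gaussian tail ~2.9e-7 per sample)
    rng = np.random.default_rng(2)
    traces = make_traces(rng.standard_normal((3, 1000)) * 0.05)
    raster = co.detect_roi_events(traces, k_sd=5.0)
    assert sum(t.size for t in raster.event_times_s) <= 1


def test_event_count_matches_generator_ground_truth():
    spec = dc.RoiSynthSpec(
        n_cells=10, baseline_duration_s=900.0, post_duration_s=0.0,
        shared_event_rate_hz=0.02, sync_corr=0.0, subtractive_shift=0.0,
        noise_sd=0.02, seed=8,
    )
    traces, gt = dc.generate_roi_population(spec)
    traces.application_time_s = 900.0  # single epoch
    raster = co.detect_roi_events(traces)
    for det, true in zip(raster.event_times_s, gt.local_event_times):
        assert abs(det.size - true.size) <= 1


def test_constant_trace_rejected():
    with pytest.raises(ValueError, match="constant trace"):
        co.detect_roi_events(make_traces(np.ones((2, 100))))


# --------------------------------------------------------------------------
# windowed correlations
# --------------------------------------------------------------------------

def test_identical_traces_fully_correlated_every_window():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(3000)
    series = co.windowed_correlations(make_traces(np.stack([x, x])), window_s=120.0, step_s=60.0)
    assert np.allclose(series.mean_pairwise, 1.0)
    assert series.matrices.shape[1:] == (2, 2)


def test_pair_count_is_n_choose_2():
    rng = np.random.default_rng(4)
    series = co.windowed_correlations(make_traces(rng.standard_normal((5, 3000))), window_s=120.0)
    iu = np.triu_indices(5, 1)
    assert iu[0].size == 10  # N(N-1)/2


def test_matrices_symmetric_unit_diagonal_bounded():
    rng = np.random.default_rng(5)
    series = co.windowed_correlations(make_traces(rng.standard_normal((6, 3000))), window_s=120.0)
    for m in series.matrices:
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.allclose(np.diag(m), 1.0)
        assert np.nanmax(np.abs(m)) <= 1.0 + 1e-12


def test_independent_noise_mean_correlation_near_zero_shrinks_with_window():
    rng = np.random.default_rng(6)
    traces = make_traces(rng.standard_normal((20, 12000)))
    out = {}
    for w in (60.0, 420.0):
        series = co.windowed_correlations(traces, window_s=w, step_s=w)
        n_samp = int(w * 5.0)
        assert abs(series.mean_pairwise.mean()) < 3.0 / np.sqrt(n_samp)
        out[w] = np.abs(series.mean_pairwise).mean()
    assert out[420.0] < out[60.0]


def test_zero_variance_cell_excluded_and_counted():
    rng = np.random.default_rng(7)
    arr = rng.standard_normal((3, 3000))
    arr[1] = 5.0  # flat cell
    with pytest.raises(ValueError):
        co.detect_roi_events(make_traces(arr))
    series = co.windowed_correlations(make_traces(arr), window_s=120.0)
    assert np.all(series.n_excluded_cells == 1)
    assert np.isfinite(series.mean_pairwise).all()


# --------------------------------------------------------------------------
# distance dependence
# --------------------------------------------------------------------------

def test_identical_epochs_give_zero_delta_and_flagged_r():
    rng = np.random.default_rng(8)
    block = rng.standard_normal((6, 3000))
    arr = np.concatenate([block, block], axis=1)
    traces = make_traces(arr)
    series = co.windowed_correlations(traces, window_s=120.0, step_s=120.0)
    res = co.distance_dependence(
        series, traces.positions_um, ((0.0, 600.0), (600.0, 1200.0))
    )
    assert np.allclose(res.delta_corr, 0.0, atol=1e-12)
    assert res.delta_fit["slope"] == pytest.approx(0.0, abs=1e-12)
    assert res.r_undefined and res.pearson_r_distance_vs_pct_change == 0.0


def test_subtractive_shift_makes_pct_change_grow_with_distance(roi_population):
    """A uniform subtractive shift leaves delta flat but makes the percent
    change larger for distant (weakly correlated) pairs: negative r."""
    spec, traces, gt = roi_population
    series = co.windowed_correlations(traces)
    res = co.distance_dependence(
        series,
        traces.positions_um,
        ((0.0, traces.application_time_s), (traces.application_time_s, traces.duration_s)),
    )
    assert res.pearson_r_distance_vs_pct_change < -0.3
    assert np.nanmean(res.delta_corr) == pytest.approx(-spec.subtractive_shift, abs=0.04)
    # delta itself is nearly distance-independent
    assert abs(res.delta_fit["slope"]) * 300.0 < 0.6 * abs(np.nanmean(res.delta_corr))


def test_shuffled_positions_kill_distance_dependence(roi_population):
    spec, traces, gt = roi_population
    series = co.windowed_correlations(traces)
    rng = np.random.default_rng(0)
    rs = []
    for _ in range(30):
        shuffled = traces.positions_um[rng.permutation(spec.n_cells)]
        res = co.distance_dependence(
            series, shuffled,
            ((0.0, traces.application_time_s), (traces.application_time_s, traces.duration_s)),
        )
        rs.append(res.pearson_r_distance_vs_pct_change)
    assert np.mean(np.abs(rs)) < 0.2


def test_post_epoch_required():
    rng = np.random.default_rng(9)
    traces = make_traces(rng.standard_normal((4, 3000)))
    series = co.windowed_correlations(traces, window_s=120.0)
    with pytest.raises(ValueError, match="post epoch"):
        co.distance_dependence(series, traces.positions_um, ((0.0, 300.0), (590.0, 600.0)))


# --------------------------------------------------------------------------
# MSD
# --------------------------------------------------------------------------

def test_msd_of_matrix_with_itself_is_zero():
    c = np.eye(4)
    assert co.matrix_msd(c, c) == 0.0


def test_msd_single_entry_perturbation_counts_twice():
    c = np.eye(5)
    c2 = c.copy()
    c2[1, 3] = c2[3, 1] = 0.2
    assert co.matrix_msd(c2, c, entries="all") == pytest.approx(0.08)
    assert co.matrix_msd(c2, c, entries="upper") == pytest.approx(0.04)


def test_msd_label_permutation_invariance():
    rng = np.random.default_rng(10)
    a = rng.standard_normal((6, 6))
    c_t = (a + a.T) / 2
    b = rng.standard_normal((6, 6))
    c_bl = (b + b.T) / 2
    perm = rng.permutation(6)
    assert co.matrix_msd(c_t, c_bl) == pytest.approx(
        co.matrix_msd(c_t[np.ix_(perm, perm)], c_bl[np.ix_(perm, perm)])
    )


def test_msd_monotone_in_perturbation_magnitude():
    c = np.eye(4)
    vals = []
    for eps in (0.1, 0.2, 0.3):
        c2 = c.copy()
        c2[0, 2] = c2[2, 0] = eps
        vals.append(co.matrix_msd(c2, c))
    assert vals == sorted(vals)


def test_msd_series_zero_for_stationary_identical_windows():
    rng = np.random.default_rng(11)
    block = rng.standard_normal((4, 600))
    arr = np.tile(block, (1, 10))
    traces = make_traces(arr, t_app=300.0)
    series = co.windowed_correlations(traces, window_s=120.0, step_s=120.0)
    ms = co.correlation_msd(traces, series, baseline_span_s=600.0)
    # every 120-s window repeats the same block, as does the baseline span
    assert np.allclose(ms.msd_raw, ms.msd_raw[0])
    assert ms.degenerate_flag or np.allclose(ms.msd_normalized[ms.baseline_window_idx].mean(), 0.0, atol=1e-8)


def test_msd_detrending_flag_with_few_baseline_windows():
    rng = np.random.default_rng(12)
    traces = make_traces(rng.standard_normal((4, 3000)), t_app=130.0)
    series = co.windowed_correlations(traces, window_s=120.0, step_s=120.0)
    ms = co.correlation_msd(traces, series, baseline_span_s=130.0)
    assert not ms.detrended_flag


def test_msd_sustained_elevation_after_subgroup_rewiring():
    """When a subgroup's coherent coupling is re-routed post-application,
    the normalized MSD stays above 3 baseline SDs even though per-cell
    event rates are unchanged."""
    spec = dc.RoiSynthSpec(seed=3, subtractive_shift=0.0, subgroup_fraction=0.4)
    traces, _ = dc.generate_roi_population(spec)
    series = co.windowed_correlations(traces)
    ms = co.correlation_msd(traces, series)
    late = ms.times_s > traces.application_time_s + 600.0
    assert ms.msd_normalized[late].min() > 3.0
    raster = co.detect_roi_events(traces)
    pre = np.mean([(t < 2700.0).sum() for t in raster.event_times_s]) / 2700.0
    post = np.mean([(t >= 2700.0).sum() for t in raster.event_times_s]) / 2700.0
    assert post == pytest.approx(pre, rel=0.15)


# --------------------------------------------------------------------------
# modulation classifier
# --------------------------------------------------------------------------

def test_exact_subtractive_recovered():
    rng = np.random.default_rng(13)
    base = rng.uniform(0.2, 0.8, 50)
    fit = co.classify_modulation(base, base - 0.1)
    assert fit.label == "subtractive"
    assert fit.shift_c == pytest.approx(0.1)


def test_exact_divisive_recovered():
    rng = np.random.default_rng(14)
    base = rng.uniform(0.2, 0.8, 50)
    fit = co.classify_modulation(base, 0.5 * base)
    assert fit.label == "divisive"
    assert fit.scale_a == pytest.approx(0.5)


def test_degenerate_baseline_indeterminate():
    base = np.full(20, 0.4)
    fit = co.classify_modulation(base, base - 0.1)
    assert fit.label == "indeterminate"


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError):
        co.classify_modulation(np.ones(5), np.ones(5))


def test_sem_conventions():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert co.sem(v, "standard") == pytest.approx(v.std(ddof=1) / 2.0)
    assert co.sem(v, "printed") == pytest.approx(v.std(ddof=1) / 4.0)
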