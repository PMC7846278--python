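"""Recurrent spiking-network model of developing-cortex spontaneous activity.

A single cortical sheet of current-based leaky integrate-and-fire neurons:
an excitatory population and an inhibitory population of which 25% are
SST+ interneurons.  Neurons sit on a 2D sheet with periodic boundaries and
connect with a distance-dependent probability
``p(d) = p0 * exp(-d^2 / (2 sigma_c^2))``.  Excitatory cells receive a
constant 50 pA drive plus a slow sinusoidal background; SST+ cells receive
40 pA.  Oxytocin is modeled purely as a depolarization of the SST+ resting
potential from -60.8 mV to -56.3 mV (the experimentally observed 4.5 mV);
everything else is held fixed.  The system runs 60 s per condition and
pairwise Pearson correlations between excitatory voltage traces, binned by
distance, quantify the resulting desynchronization.

Intrinsic parameters beyond the printed ones are free configuration; the
defaults place the baseline SST rheobase just above the 40 pA drive so
that the resting-potential shift converts SST cells from near-silent to
tonically active.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LifParams",
    "ModelConfig",
    "Connectivity",
    "SimResult",
    "CorrelationByDistance",
    "build_network",
    "apply_oxytocin",
    "simulate",
    "simulate_condition",
    "model_fi_curve",
    "voltage_correlations",
    "toroidal_distances",
]

POP_E, POP_PV, POP_SST = 0, 1, 2


@dataclass(frozen=True)
class LifParams:
    """Leaky integrate-and-fire parameters (pF, nS, mV, ms)."""

    c_pf: float
    g_l_ns: float
    v_rest_mv: float
    v_th_mv: float
    v_reset_mv: float
    t_ref_ms: float

    def __post_init__(self) -> None:
        if self.v_reset_mv >= self.v_th_mv:
            raise ValueError("V_reset must be below V_th")
        if self.c_pf <= 0 or self.g_l_ns <= 0:
            raise ValueError("capacitance and leak conductance must be positive")

    @property
    def tau_ms(self) -> float:
        return self.c_pf / self.g_l_ns

    @property
    def rheobase_pa(self) -> float:
        return self.g_l_ns * (self.v_th_mv - self.v_rest_mv)


@dataclass
class ModelConfig:
    n_excitatory: int = 1600
    n_inhibitory: int = 400
    sst_fraction_of_inhibitory: float = 0.25
    sheet_size_um: float = 1000.0
    periodic: bool = True

    e_params: LifParams = field(
        default_factory=lambda: LifParams(30.0, 3.0, -65.0, -46.5, -60.0, 2.0)
    )
    pv_params: LifParams = field(
        default_factory=lambda: LifParams(20.0, 2.5, -65.0, -47.0, -60.0, 1.5)
    )
    sst_params: LifParams = field(
        default_factory=lambda: LifParams(25.0, 2.5, -60.8, -44.0, -56.5, 2.0)
    )
    sst_v_rest_oxytocin_mv: float = -56.3

    w_e_pa: float = 12.0  # synaptic-current jump per excitatory spike
    w_i_pa: float = -40.0
    tau_syn_e_ms: float = 5.0
    tau_syn_i_ms: float = 10.0
    delay_ms: float = 1.0
    p0_e: float = 0.4
    p0_i: float = 0.8
    sigma_c_e_um: float = 200.0
    sigma_c_i_um: float = 200.0

    i_ext_e_pa: float = 50.0
    i_ext_sst_pa: float = 40.0
    i_ext_pv_pa: float = 0.0
    bg_sin_amp_pa: float = 15.0
    bg_sin_freq_hz: float = 0.5
    bg_sin_offset_pa: float = 0.0
    noise_sd_pa: float = 12.0
    noise_tau_ms: float = 5.0

    duration_s: float = 60.0
    dt_ms: float = 0.1
    n_record_e: int = 100
    record_dt_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sst_fraction_of_inhibitory <= 1.0:
            raise ValueError("sst_fraction_of_inhibitory must be in (0, 1]")
        if self.dt_ms > 0.1 + 1e-12:
            raise ValueError("dt must be <= 0.1 ms")
        for p0 in (self.p0_e, self.p0_i):
            if not 0.0 <= p0 <= 1.0:
                raise ValueError("connection probability p(d) must stay in [0, 1]")
        if self.w_e_pa < 0 or self.w_i_pa > 0:
            raise ValueError("excitatory weight must be >= 0 and inhibitory <= 0")

    @property
    def n_total(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    @property
    def n_sst(self) -> int:
        return int(round(self.sst_fraction_of_inhibitory * self.n_inhibitory))


def apply_oxytocin(config: ModelConfig) -> ModelConfig:
    """Return a config identical except for the SST resting potential.

    Idempotent: applying twice changes nothing further.
    """
    new_sst = replace(config.sst_params, v_rest_mv=config.sst_v_rest_oxytocin_mv)
    return replace(config, sst_params=new_sst)


# --------------------------------------------------------------------------
# connectivity
# --------------------------------------------------------------------------

@dataclass
class Connectivity:
    positions_um: np.ndarray  # (N, 2)
    population: np.ndarray  # POP_E / POP_PV / POP_SST per neuron
    targets: list[np.ndarray]  # out-edges per presynaptic neuron
    weights_pa: np.ndarray  # weight carried by each presynaptic neuron's spikes

    @property
    def n_edges(self) -> int:
        return int(sum(t.size for t in self.targets))


def toroidal_distances(a_um: np.ndarray, b_um: np.ndarray, size_um: float, periodic: bool = True) -> np.ndarray:
    """Pairwise Euclidean distances, optionally on the torus."""
    d = np.abs(a_um[:, None, :] - b_um[None, :, :])
    if periodic:
        d = np.minimum(d, size_um - d)
    return np.sqrt((d ** 2).sum(-1))


def build_network(config: ModelConfig, rng: np.random.Generator | None = None) -> Connectivity:
    """Sample positions and distance-dependent connectivity.

    Each directed pair is connected with probability
    ``p0 * exp(-d^2 / (2 sigma_c^2))`` (per presynaptic class), using the
    toroidal metric; no self-connections.  Excitatory out-weights are
    ``w_e_pa > 0``, inhibitory out-weights ``w_i_pa < 0``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(0,)))
    n = config.n_total
    pos = rng.uniform(0.0, config.sheet_size_um, size=(n, 2))
    pop = np.full(n, POP_E, dtype=np.int8)
    pop[config.n_excitatory :] = POP_PV
    pop[config.n_excitatory : config.n_excitatory + config.n_sst] = POP_SST

    dist = toroidal_distances(pos, pos, config.sheet_size_um, config.periodic)
    is_exc = pop == POP_E
    p0 = np.where(is_exc, config.p0_e, config.p0_i)[:, None]
    sig = np.where(is_exc, config.sigma_c_e_um, config.sigma_c_i_um)[:, None]
    prob = p0 * np.exp(-(dist ** 2) / (2.0 * sig ** 2))
    if np.any(prob > 1.0 + 1e-12):
        raise ValueError("connection probability p(d) exceeds 1")
    np.fill_diagonal(prob, 0.0)
    adj = rng.random((n, n)) < prob  # adj[pre, post]
    targets = [np.flatnonzero(adj[i]) for i in range(n)]
    weights = np.where(is_exc, config.w_e_pa, config.w_i_pa)
    return Connectivity(positions_um=pos, population=pop, targets=targets, weights_pa=weights)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class SimResult:
    condition: str  # "baseline" | "oxytocin"
    spike_times_s: list[np.ndarray]
    positions_um: np.ndarray
    population: np.ndarray
    recorded_idx: np.ndarray
    voltages_mv: np.ndarray  # (n_recorded, T_rec)
    record_dt_ms: float
    duration_s: float

    def mean_rate_hz(self, pop_code: int | None = None) -> float:
        sel = np.ones(self.population.size, bool) if pop_code is None else self.population == pop_code
        counts = np.array([self.spike_times_s[i].size for i in np.flatnonzero(sel)])
        return float(counts.mean() / self.duration_s)


class _NetState:
    """Mutable integration state carried across conditions."""

    def __init__(self, config: ModelConfig, conn: Connectivity, rng: np.random.Generator):
        n = config.n_total
        self.v = np.empty(n)
        self.syn_e = np.zeros(n)
        self.syn_i = np.zeros(n)
        self.noise = np.zeros(n)
        self.ref_left = np.zeros(n, dtype=np.int64)
        self.queue: deque[np.ndarray] = deque(
            [np.empty(0, dtype=np.intp)] * max(1, int(round(config.delay_ms / config.dt_ms)))
        )
        self.rng = rng
        self.t_offset_s = 0.0


def _pop_arrays(config: ModelConfig, pop: np.ndarray, sst_v_rest: float | None = None):
    params = {POP_E: config.e_params, POP_PV: config.pv_params, POP_SST: config.sst_params}
    v_rest = np.empty(pop.size)
    g_l = np.empty(pop.size)
    v_th = np.empty(pop.size)
    v_reset = np.empty(pop.size)
    tau = np.empty(pop.size)
    t_ref = np.empty(pop.size)
    for code, p in params.items():
        m = pop == code
        vr = p.v_rest_mv
        if code == POP_SST and sst_v_rest is not None:
            vr = sst_v_rest
        v_rest[m], g_l[m], v_th[m], v_reset[m] = vr, p.g_l_ns, p.v_th_mv, p.v_reset_mv
        tau[m], t_ref[m] = p.tau_ms, p.t_ref_ms
    return v_rest, g_l, v_th, v_reset, tau, t_ref


def simulate_condition(
    config: ModelConfig,
    conn: Connectivity,
    state: _NetState,
    condition: str,
) -> SimResult:
    """Integrate one 60-s (default) condition, mutating ``state``.

    Exponential (exact leak) update at fixed dt with exponential synaptic
    currents, an Ornstein-Uhlenbeck current noise, the sinusoidal
    background on excitatory cells, and delayed spike delivery.  Aborts on
    numerical divergence (|V| > 200 mV).
    """
    dt = config.dt_ms
    n_steps = int(round(config.duration_s * 1000.0 / dt))
    pop = conn.population
    sst_vr = config.sst_params.v_rest_mv if condition == "baseline" else config.sst_v_rest_oxytocin_mv
    v_rest, g_l, v_th, v_reset, tau, t_ref = _pop_arrays(config, pop, sst_vr)
    ref_steps = np.maximum(1, np.round(t_ref / dt)).astype(np.int64)

    i_ext = np.zeros(pop.size)
    i_ext[pop == POP_E] = config.i_ext_e_pa
    i_ext[pop == POP_PV] = config.i_ext_pv_pa
    i_ext[pop == POP_SST] = config.i_ext_sst_pa
    is_e = pop == POP_E

    dec_e = math.exp(-dt / config.tau_syn_e_ms)
    dec_i = math.exp(-dt / config.tau_syn_i_ms)
    dec_m = np.exp(-dt / tau)
    noise_a = dt / config.noise_tau_ms
    noise_b = config.noise_sd_pa * math.sqrt(2.0 * dt / config.noise_tau_ms)

    rec_stride = max(1, int(round(config.record_dt_ms / dt)))
    rec_idx = state.rec_idx
    n_rec_steps = n_steps // rec_stride
    volts = np.empty((rec_idx.size, n_rec_steps))
    spikes: list[list[float]] = [[] for _ in range(pop.size)]
    w_omega = 2.0 * math.pi * config.bg_sin_freq_hz

    v, syn_e, syn_i = state.v, state.syn_e, state.syn_i
    noise, ref_left, queue, rng = state.noise, state.ref_left, state.queue, state.rng
    rec_col = 0
    for step in range(n_steps):
        t_s = state.t_offset_s + step * dt / 1000.0
        syn_e *= dec_e
        syn_i *= dec_i
        arriving = queue.popleft()
        for pre in arriving:
            w = conn.weights_pa[pre]
            tgt = conn.targets[pre]
            if w >= 0:
                syn_e[tgt] += w
            else:
                syn_i[tgt] += w
        noise += noise_a * (-noise) + noise_b * rng.standard_normal(pop.size)
        i_total = syn_e + syn_i + i_ext + noise
        if config.bg_sin_amp_pa != 0.0 or config.bg_sin_offset_pa != 0.0:
            i_total[is_e] += config.bg_sin_offset_pa + config.bg_sin_amp_pa * math.sin(w_omega * t_s)
        v_inf = v_rest + i_total / g_l
        v[:] = v_inf + (v - v_inf) * dec_m
        refractory = ref_left > 0
        v[refractory] = v_reset[refractory]
        ref_left[refractory] -= 1
        spiking = np.flatnonzero((v >= v_th) & ~refractory)
        if spiking.size:
            t_spk = t_s + dt / 1000.0
            for i in spiking:
                spikes[i].append(t_spk)
            v[spiking] = v_reset[spiking]
            ref_left[spiking] = ref_steps[spiking]
        queue.append(spiking)
        if (step + 1) % rec_stride == 0 and rec_col < n_rec_steps:
            volts[:, rec_col] = v[rec_idx]
            rec_col += 1
        if step % 10000 == 0 and np.abs(v).max() > 200.0:
            raise RuntimeError(
                f"numerical divergence at t={t_s:.3f} s: |V|max = {np.abs(v).max():.1f} mV"
            )
    state.t_offset_s += config.duration_s
    t0 = state.t_offset_s - config.duration_s
    return SimResult(
        condition=condition,
        spike_times_s=[np.array(s) - t0 for s in spikes],
        positions_um=conn.positions_um,
        population=pop,
        recorded_idx=rec_idx,
        voltages_mv=volts,
        record_dt_ms=config.record_dt_ms,
        duration_s=config.duration_s,
    )


def simulate(
    config: ModelConfig,
    connectivity: Connectivity | None = None,
) -> tuple[SimResult, SimResult]:
    """Run baseline then oxytocin on the same network realization.

    Only the SST resting potential differs between conditions; the network,
    noise stream and dynamical state are continuous across the switch.
    Identical config + seed give identical spike trains.
    """
    conn = connectivity if connectivity is not None else build_network(config)
    rng_init = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(1,)))
    rng_noise = np.random.default_rng(np.random.SeedSequence(entropy=int(config.seed), spawn_key=(2,)))
    state = _NetState(config, conn, rng_noise)
    v_rest0 = _pop_arrays(config, conn.population)[0]
    state.v = v_rest0 + rng_init.uniform(-2.0, 2.0, conn.population.size)
    e_idx = np.flatnonzero(conn.population == POP_E)
    state.rec_idx = e_idx[: min(config.n_record_e, e_idx.size)]
    base = simulate_condition(config, conn, state, "baseline")
    oxt = simulate_condition(config, conn, state, "oxytocin")
    return base, oxt


# --------------------------------------------------------------------------
# f-I curves
# --------------------------------------------------------------------------

def _isolated_rate(p: LifParams, i_pa: float, duration_s: float = 5.0, dt_ms: float = 0.1) -> float:
    """Simulated firing rate of one LIF neuron at constant current.

    Exact exponential integration with interpolated threshold crossings and
    refractory carry-over; the rate is the inverse of the mean steady-state
    ISI (first spike discarded).
    """
    tau = p.tau_ms
    v_inf = p.v_rest_mv + i_pa / p.g_l_ns
    v = p.v_rest_mv
    t = 0.0
    total = duration_s * 1000.0
    spikes: list[float] = []
    while t < total:
        step = min(dt_ms, total - t)
        decay = math.exp(-step / tau)
        v_new = v_inf + (v - v_inf) * decay
        if v_new >= p.v_th_mv and v_inf > p.v_th_mv:
            # invert the exponential for the crossing time within the step
            t_cross = t + tau * math.log((v_inf - v) / (v_inf - p.v_th_mv))
            spikes.append(t_cross)
            t = t_cross + p.t_ref_ms
            v = p.v_reset_mv
        else:
            v = v_new
            t += step
    if len(spikes) < 3:
        return 0.0
    isis = np.diff(spikes[1:])
    return float(1000.0 / isis.mean()) if isis.size else 0.0


def model_fi_curve(
    config: ModelConfig,
    currents_pa: np.ndarray,
    population: str = "sst",
    duration_s: float = 5.0,
) -> dict[str, np.ndarray]:
    """f-I curves of an isolated neuron in baseline and oxytocin.

    Weights play no role (the neuron is isolated); only the SST resting
    potential differs between conditions.
    """
    params = {"e": config.e_params, "pv": config.pv_params, "sst": config.sst_params}[population]
    base = np.array([_isolated_rate(params, i, duration_s, config.dt_ms) for i in currents_pa])
    if population == "sst":
        p_oxt = replace(params, v_rest_mv=config.sst_v_rest_oxytocin_mv)
    else:
        p_oxt = params
    oxt = np.array([_isolated_rate(p_oxt, i, duration_s, config.dt_ms) for i in currents_pa])
    return {"currents_pa": np.asarray(currents_pa, dtype=float), "baseline_hz": base, "oxytocin_hz": oxt}


# --------------------------------------------------------------------------
# voltage correlations by distance
# --------------------------------------------------------------------------

@dataclass
class CorrelationByDistance:
    bin_edges_um: np.ndarray
    bin_centers_um: np.ndarray
    baseline_corr: np.ndarray
    oxytocin_corr: np.ndarray
    delta_corr: np.ndarray
    n_pairs: np.ndarray
    n_excluded_traces: int = 0


def voltage_correlations(
    result_baseline: SimResult,
    result_oxytocin: SimResult,
    bin_edges_um: np.ndarray,
    sheet_size_um: float,
    periodic: bool = True,
) -> CorrelationByDistance:
    """Binned pairwise Pearson correlations of excitatory voltage traces.

    Unclipped voltages are used (spike resets included); constant traces
    are excluded with a count.  ``delta`` is oxytocin minus baseline.
    """
    if result_baseline.recorded_idx.size < 2:
        raise ValueError("need at least 2 recorded excitatory voltages")
    edges = np.asarray(bin_edges_um, dtype=float)
    pos = result_baseline.positions_um[result_baseline.recorded_idx]
    dist = toroidal_distances(pos, pos, sheet_size_um, periodic)
    iu = np.triu_indices(pos.shape[0], k=1)

    def _corr(volts: np.ndarray) -> tuple[np.ndarray, int]:
        sd = volts.std(axis=1)
        good = sd > 0
        c = np.full((volts.shape[0], volts.shape[0]), np.nan)
        if good.sum() >= 2:
            c[np.ix_(good, good)] = np.corrcoef(volts[good])
        return c[iu], int((~good).sum())

    cb, nb = _corr(result_baseline.voltages_mv)
    co, no = _corr(result_oxytocin.voltages_mv)
    d = dist[iu]
    n_bins = edges.size - 1
    base = np.full(n_bins, np.nan)
    oxt = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = (d >= edges[b]) & (d < edges[b + 1]) & np.isfinite(cb) & np.isfinite(co)
        n_pairs[b] = int(sel.sum())
        if n_pairs[b]:
            base[b] = cb[sel].mean()
            oxt[b] = co[sel].mean()
    return CorrelationByDistance(
        bin_edges_um=edges,
        bin_centers_um=(edges[:-1] + edges[1:]) / 2.0,
        baseline_corr=base,
        oxytocin_corr=oxt,
        delta_corr=oxt - base,
        n_pairs=n_pairs,
        n_excluded_traces=nb + no,
    )
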