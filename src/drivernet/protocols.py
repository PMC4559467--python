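"""Experiment orchestration.

The experiments come in two families:

* **Network-scale**: a plastic transient run to weight-distribution
  equilibrium (with divergence guard and Kolmogorov-Smirnov convergence
  criterion), the two-pulse driver-group stimulation with PSTH readout,
  and realization ensembles over a fixed topology.
* **Reduced validation models** for the mean-field theory: the
  two-neuron inhibitory pair (stationary weight vs base rate), the
  fan-in competition of 80 plastic synapses under normalization, and
  the frozen-weight two-neuron excitatory pair sampling the mean STDP
  update per presynaptic spike.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from . import _kernel
from .analysis import detect_drivers_percentile, psth
from .dynamics import (DEFAULT_DT, DriveSpec, NetworkState, SpikeRecord,
                       StimulusSpec, apply_stimulus_protocol, run_simulation)
from .plasticity import PlasticityConfig, STDPParams
from .topology import NeuronParams, SynapseParams, Topology

__all__ = [
    "ExperimentSpec",
    "TransientResult",
    "derive_seed",
    "run_transient_to_equilibrium",
    "run_driver_stimulation",
    "run_realization_ensemble",
    "run_two_neuron_inhibitory",
    "run_fan_in_competition",
    "run_two_neuron_excitatory_dw",
]


def derive_seed(master: int, tag: str) -> int:
    """Stable per-component substream seed below 2**31: mixing the master
    seed with a component tag keeps streams independent and means that
    toggling one component never perturbs another's randomness."""
    h = zlib.crc32(tag.encode()) & 0xFFFFFFFF
    mixed = np.random.SeedSequence([int(master) & 0x7FFFFFFF, h])
    return int(mixed.generate_state(1)[0] % (2 ** 31))


@dataclass
class ExperimentSpec:
    """Configuration of a plastic transient run.

    The reduced-scale defaults (800 E + 200 I, 30 biological minutes)
    keep the in-degree statistics in a regime where heterogeneity-driven
    symmetry breaking still occurs while remaining desk-computable; the
    base model's full scale (4000 + 1000, ~5 h) is reached with
    ``scale_factor=5`` and a longer duration.
    """

    name: str = "reduced"
    n_e: int = 800
    n_i: int = 200
    drive: DriveSpec = field(default_factory=DriveSpec)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    duration: float = 30 * 60 * 1000.0     # transient length (ms)
    snapshot_interval: float = 10 * 60 * 1000.0  # KS check cadence (ms)
    ks_tolerance: float = 0.01             # consecutive-snapshot KS distance
    record_tail: float = 100_000.0         # spike record kept from the end (ms)
    dt: float = DEFAULT_DT
    seed: int = 0
    rate_ceiling: float = 100.0            # divergence guard (Hz over 10 s)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)


@dataclass
class TransientResult:
    topology: Topology
    state: NetworkState
    spikes_tail: SpikeRecord
    weight_trajectory: list
    converged: bool
    elapsed: float  # ms of biological time actually simulated


def run_transient_to_equilibrium(spec: ExperimentSpec,
                                 topology: Topology) -> TransientResult:
    """Run the plastic network until the E-E weight distribution stops
    moving (KS distance between snapshots ``snapshot_interval`` apart
    below ``ks_tolerance``) or the duration budget is exhausted.

    A sustained mean population rate above the ceiling aborts with
    :class:`DivergenceError`.
    """
    pc = spec.plasticity
    if pc is None or (pc.ee_stdp is None and pc.ie_stdp is None
                      and pc.normalization is None and pc.scaling is None):
        raise ValueError("transient protocol requires some plasticity enabled")
    topo = topology
    state = None
    trajectory = []
    tails: list[SpikeRecord] = []
    prev_weights = None
    converged = False
    elapsed = 0.0
    seg = 0
    while elapsed < spec.duration and not converged:
        seg_dur = min(spec.snapshot_interval, spec.duration - elapsed)
        res = run_simulation(
            topo, spec.drive, seg_dur, spec.dt, pc,
            neuron=spec.neuron, synapse=spec.synapse,
            seed=derive_seed(spec.seed, f"{spec.name}/segment{seg}"),
            initial_state=state,
            record_spikes=True,
            record_from=max(0.0, seg_dur - spec.record_tail),
            snapshot_interval=seg_dur, snapshot_full=False,
            rate_ceiling=spec.rate_ceiling)
        topo, state = res.topology, res.state
        trajectory.extend(res.weight_trajectory)
        tails.append(res.spikes)
        if len(tails) > 2:
            tails.pop(0)
        ee = topo.w["ee"].data
        if prev_weights is not None and ee.size:
            ks = sstats.ks_2samp(prev_weights, ee).statistic
            if ks < spec.ks_tolerance:
                converged = True
        prev_weights = ee.copy()
        elapsed += seg_dur
        seg += 1
    # stitch the recorded per-segment (run-relative) tails into absolute time
    offs = elapsed - sum(r.duration for r in tails)
    times = np.concatenate([r.times + offs + sum(t.duration for t in tails[:k])
                            for k, r in enumerate(tails)]) if tails else np.empty(0)
    ids = np.concatenate([r.ids for r in tails]) if tails else np.empty(0, int)
    tail = SpikeRecord(times, ids, topo.n_e, topo.n_i, elapsed)
    return TransientResult(topo, state, tail, trajectory, converged, elapsed)


def run_driver_stimulation(topology: Topology, state: NetworkState,
                           group, protocol: StimulusSpec | None = None,
                           n_trials: int = 10, seed: int = 0,
                           drive: DriveSpec = DriveSpec(),
                           window: float = 100.0,
                           washout_mean: float = 2000.0,
                           dt: float = DEFAULT_DT,
                           neuron: NeuronParams = NeuronParams(),
                           synapse: SynapseParams = SynapseParams()):
    """Two-pulse stimulation of a cell group, repeated over trials.

    Each trial continues the network from a fresh dynamical state (an
    exponentially distributed washout, mean 2 s, separates trials),
    requires no targeted cell to be refractory at onset (otherwise the
    washout continues), stimulates, and records ``window`` ms before and
    after.  Plasticity is frozen throughout (the equilibrium network is
    probed, not retrained).

    Returns a dict with the trial-averaged excitatory PSTH (1 ms bins,
    time 0 = end of stimulation) and ``ratio``, the mean excitatory rate
    in (0, window] over the rate in (-window, 0] (pre-stimulus).
    """
    group = list(group)
    if not group:
        raise ValueError("group must be non-empty")
    if protocol is None:
        protocol = StimulusSpec(target_ids=tuple(group))
    else:
        protocol = StimulusSpec(tuple(group), protocol.pulse_duration,
                                protocol.inter_pulse_gap, protocol.amplitude,
                                protocol.n_pulses)
    rng = np.random.default_rng(derive_seed(seed, "stimulation/washout"))
    st = state.copy()
    pre_rates, post_rates = [], []
    psth_acc = None
    edges = None
    n_done = 0
    n_stim_spikes = 0
    attempts = 0
    while n_done < n_trials:
        attempts += 1
        if attempts > 20 * n_trials:
            raise RuntimeError("could not find non-refractory stimulation onsets")
        wash = float(rng.exponential(washout_mean)) + dt
        res = run_simulation(topology, drive, wash, dt, None, neuron, synapse,
                             seed=derive_seed(seed, f"stim/wash{attempts}"),
                             initial_state=st, record_spikes=False)
        st = res.state
        pre = run_simulation(topology, drive, window, dt, None, neuron,
                             synapse,
                             seed=derive_seed(seed, f"stim/pre{attempts}"),
                             initial_state=st)
        if np.any(pre.state.refractory_remaining[group] > 0):
            st = pre.state
            continue
        st = pre.state
        st2, stim_rec, ok = apply_stimulus_protocol(
            st, topology, protocol, dt, drive, neuron, synapse)
        if not ok:
            continue
        st = st2
        n_stim_spikes += int(np.sum(np.isin(stim_rec.ids, group)))
        stim_len = stim_rec.duration
        post = run_simulation(topology, drive, window, dt, None, neuron,
                              synapse,
                              seed=derive_seed(seed, f"stim/post{attempts}"),
                              initial_state=st)
        st = post.state
        # assemble one spike list on the trial's time axis, 0 = end of stim
        t = np.concatenate([pre.spikes.times - window - stim_len,
                            stim_rec.times - stim_len,
                            post.spikes.times])
        i = np.concatenate([pre.spikes.ids, stim_rec.ids, post.spikes.ids])
        trial = SpikeRecord(t[np.argsort(t, kind="stable")],
                            i[np.argsort(t, kind="stable")],
                            topology.n_e, topology.n_i, window)
        c, r = psth(trial, 1.0, [0.0], window=(-window - stim_len, window))
        if psth_acc is None:
            psth_acc, edges = r, c
        else:
            psth_acc = psth_acc + r
        e_mask = trial.ids < topology.n_e
        te = trial.times[e_mask]
        pre_rates.append(np.sum((te > -window - stim_len) & (te <= -stim_len))
                         / (topology.n_e * window / 1000.0))
        post_rates.append(np.sum((te > 0) & (te <= window))
                          / (topology.n_e * window / 1000.0))
        n_done += 1
    pre_m = float(np.mean(pre_rates))
    post_m = float(np.mean(post_rates))
    if pre_m > 0:
        ratio = post_m / pre_m
    else:
        # silent network: no change unless the stimulation echoes into the
        # post window
        ratio = 1.0 if post_m == 0 else float("inf")
    return {
        "psth_lags": edges,
        "psth": psth_acc / n_done,
        "pre_rate": pre_m,
        "post_rate": post_m,
        "ratio": ratio,
        "n_trials": n_done,
        "n_stimulated_spikes": n_stim_spikes,
        "state": st,
    }


def run_realization_ensemble(topology: Topology, n_realizations: int,
                             seed: int = 0,
                             spec: ExperimentSpec | None = None,
                             driver_fraction: float = 0.005) -> np.ndarray:
    """Relative frequency of driver-group membership per excitatory cell
    over repeated plastic transients with the *same* topology but varying
    initial conditions and input noise (Poisson drive substreams).

    Returns an array of length n_e with values in [0, 1].
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    base = spec or ExperimentSpec()
    counts = np.zeros(topology.n_e)
    for r in range(n_realizations):
        s = ExperimentSpec(
            name=f"{base.name}/real{r}", n_e=topology.n_e, n_i=topology.n_i,
            drive=DriveSpec(mode="poisson",
                            depolarization=base.drive.depolarization),
            plasticity=base.plasticity, duration=base.duration,
            snapshot_interval=base.snapshot_interval,
            ks_tolerance=base.ks_tolerance, record_tail=base.record_tail,
            dt=base.dt, seed=derive_seed(seed, f"ensemble/{r}"),
            rate_ceiling=base.rate_ceiling, neuron=base.neuron,
            synapse=base.synapse)
        res = run_transient_to_equilibrium(s, topology)
        rep = detect_drivers_percentile(res.topology, driver_fraction)
        counts[rep.driver_ids] += 1.0
    return counts / n_realizations


# ---------------------------------------------------------------------------
# reduced two-neuron / fan-in validation models
# ---------------------------------------------------------------------------

def run_two_neuron_inhibitory(nu_0_grid, duration: float = 100.0,
                              seed: int = 0, nu_inh: float = 5.0,
                              A_plus: float = 0.02, A_minus: float = 0.005,
                              tau: float = 20.0, delta_v: float = 10.0,
                              w_cap: float = 5.0, w0: float = 1.0,
                              tail_fraction: float = 0.25) -> dict:
    """Two-cell validation of the stationary inhibitory weight.

    The postsynaptic cell integrates linearly at rate nu0 * delta_v per
    second (so it fires at nu0 without inhibition); the presynaptic cell
    fires Poisson at ``nu_inh``; each presynaptic spike subtracts the
    current weight w (mV, delta synapse, no lower clamping - the
    derivation's linear-rise assumption).  Nearest-neighbour STDP with
    potentiation/depression amplitudes A_plus/A_minus updates w, clipped
    to [0, w_cap].  ``duration`` in seconds per grid point.

    Returns dict with arrays nu_0, w_mean (time-averaged weight over the
    final ``tail_fraction`` of the run) and w_sd.
    """
    nu_0_grid = np.asarray(nu_0_grid, dtype=float)
    tau_s = tau / 1000.0
    w_mean = np.empty_like(nu_0_grid)
    w_sd = np.empty_like(nu_0_grid)
    for gi, nu0 in enumerate(nu_0_grid):
        if nu0 <= 0:
            raise ValueError("base rates must be positive")
        rng = np.random.default_rng(derive_seed(seed, f"two_inh/{gi}"))
        slope = nu0 * delta_v          # mV per s
        x = 0.0                        # potential above rest (mV)
        w = float(w0)
        t = 0.0
        t_next_pre = rng.exponential(1.0 / nu_inh)
        last_post = -math.inf
        z = 0.0                        # pre spikes since last post, decayed
        z_t = 0.0
        t_tail = (1.0 - tail_fraction) * duration
        # w is piecewise constant between events; integrate over the tail
        acc_w = acc_w2 = acc_t = 0.0
        while t < duration:
            t_post = t + (delta_v - x) / slope
            t_event = min(t_next_pre, t_post, duration)
            if t_event > t_tail:       # time-weighted tail statistics
                seg = t_event - max(t, t_tail)
                acc_w += w * seg
                acc_w2 += w * w * seg
                acc_t += seg
            if t_event >= duration:
                break
            x += slope * (t_event - t)
            t = t_event
            if t_next_pre <= t_post:   # presynaptic inhibitory spike
                x -= w                 # delta IPSP, unclamped (linear model)
                if math.isfinite(last_post):
                    w = max(0.0, min(
                        w_cap,
                        w - A_minus * math.exp(-(t - last_post) / tau_s)))
                z = z * math.exp(-(t - z_t) / tau_s) + 1.0
                z_t = t
                t_next_pre = t + rng.exponential(1.0 / nu_inh)
            else:                      # postsynaptic spike
                x = 0.0
                w = max(0.0, min(
                    w_cap,
                    w + A_plus * z * math.exp(-(t - z_t) / tau_s)))
                z = 0.0
                z_t = t
                last_post = t
        if acc_t > 0:
            w_mean[gi] = acc_w / acc_t
            w_sd[gi] = math.sqrt(max(0.0, acc_w2 / acc_t
                                     - (acc_w / acc_t) ** 2))
        else:
            w_mean[gi], w_sd[gi] = w, 0.0
    return {"nu_0": nu_0_grid, "w_mean": w_mean, "w_sd": w_sd}


def run_fan_in_competition(n_syn: int = 80, fast_ids=tuple(range(10)),
                           fast_rate: float = 25.0, slow_rate: float = 5.0,
                           duration: float = 500.0, seed: int = 0,
                           dt: float = DEFAULT_DT,
                           drive: float = 6.0, w0: float = 1.0,
                           ee_stdp: STDPParams | None = None,
                           norm_interval: float = 100.0,
                           record_interval: float = 1000.0,
                           neuron: NeuronParams = NeuronParams(),
                           synapse: SynapseParams = SynapseParams()) -> dict:
    """Fan-in competition: ``n_syn`` Poisson inputs with plastic E-E STDP
    synapses converge onto one LIF cell under incoming-sum normalization.

    ``fast_ids`` fire at ``fast_rate`` Hz, the rest at ``slow_rate`` Hz;
    the faster presynaptic group wins the competition over the fixed
    total weight.  ``duration`` in seconds.  Returns per-synapse weight
    trajectories sampled every ``record_interval`` ms.
    """
    from .plasticity import EE_STDP

    p = ee_stdp or EE_STDP()
    fast = np.zeros(n_syn, dtype=bool)
    fast[list(fast_ids)] = True
    rate_p = np.where(fast, fast_rate, slow_rate) * dt / 1000.0
    w = np.full(n_syn, w0)
    n_steps = int(round(duration * 1000.0 / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    w_out = np.zeros((n_steps // rec_every, n_syn))
    tm, te = neuron.tau_m, synapse.tau_e
    a_m = math.exp(-dt / tm)
    a_e = math.exp(-dt / te)
    k_e = abs(synapse.c_e_norm) * te / (tm - te) * (a_m - a_e)
    scale = p.w_max if p.effective_scaling else 1.0
    n_post = _kernel.fan_in_steps(
        n_steps, n_syn, rate_p, w,
        a_m, a_e, k_e, neuron.E_L, neuron.V_thres, neuron.V_reset,
        int(math.ceil(neuron.tau_ref / dt)), drive,
        p.A_plus * scale, p.A_minus * scale,
        math.exp(-dt / p.tau_plus), math.exp(-dt / p.tau_minus), p.w_max,
        max(1, int(round(norm_interval / dt))), float(n_syn) * w0,
        rec_every, w_out, derive_seed(seed, "fan_in"))
    return {
        "weights": w, "trajectory": w_out, "fast_mask": fast,
        "post_rate": n_post / duration,
        "record_interval": record_interval,
    }


def run_two_neuron_excitatory_dw(w_grid, duration: float = 500.0,
                                 n_repeats: int = 10, seed: int = 0,
                                 n_inputs: int = 1650,
                                 input_rate: float = 1.0,
                                 input_strength: float = 0.5,
                                 A_plus: float = 0.02, A_minus: float = 0.021,
                                 tau: float = 20.0, dt: float = DEFAULT_DT,
                                 neuron: NeuronParams = NeuronParams(),
                                 collect_v: bool = True) -> dict:
    """Frozen-weight sampling of the mean excitatory STDP update.

    Two LIF cells are driven by independent Poisson bombardment
    (``n_inputs`` delta synapses of ``input_strength`` mV at
    ``input_rate`` Hz each) and connected by a delta synapse of fixed
    strength w (mV); nearest-neighbour STDP updates are accumulated but
    not applied, so the mean update per presynaptic spike is sampled at
    fixed w.  ``duration`` in seconds per repeat.

    Returns dict with arrays over the grid: dw_mean, dw_sd (over
    repeats), rate_post (Hz), plus pooled subthreshold voltage samples
    of the postsynaptic cell (for the membrane-potential distribution)
    and the presynaptic rate.
    """
    w_grid = np.asarray(w_grid, dtype=float)
    n_steps = int(round(duration * 1000.0 / dt))
    lam = n_inputs * input_rate * dt / 1000.0
    a_m = math.exp(-dt / neuron.tau_m)
    dec = math.exp(-dt / tau)
    ref_steps = int(math.ceil(neuron.tau_ref / dt))
    dw_mean = np.empty(w_grid.size)
    dw_sd = np.empty(w_grid.size)
    rate_post = np.empty(w_grid.size)
    rate_pre = np.empty(w_grid.size)
    v_samples_all = []
    for gi, w in enumerate(w_grid):
        per = []
        posts = []
        pres = []
        for rep in range(n_repeats):
            want_v = collect_v and gi == 0
            v_buf = np.empty(n_steps // 10 + 1 if want_v else 1)
            n_pre, n_post, dw, n_v = _kernel.two_neuron_frozen_steps(
                n_steps, lam, input_strength, float(w),
                a_m, neuron.E_L, neuron.V_thres, neuron.V_reset, ref_steps,
                dec, A_plus, A_minus,
                10 if want_v else 0, v_buf,
                derive_seed(seed, f"two_exc/{gi}/{rep}"))
            per.append(dw / n_pre if n_pre else 0.0)
            posts.append(n_post / duration)
            pres.append(n_pre / duration)
            if want_v:
                v_samples_all.append(v_buf[:n_v])
        per = np.asarray(per)
        dw_mean[gi] = per.mean()
        dw_sd[gi] = per.std(ddof=1) if n_repeats > 1 else 0.0
        rate_post[gi] = float(np.mean(posts))
        rate_pre[gi] = float(np.mean(pres))
    return {
        "w": w_grid, "dw_mean": dw_mean, "dw_sd": dw_sd,
        "rate_post": rate_post, "rate_pre": rate_pre,
        "v_samples": (np.concatenate(v_samples_all)
                      if v_samples_all else np.empty(0)),
    }
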