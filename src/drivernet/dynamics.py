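"""Clock-driven simulation of the balanced network.

Leaky integrate-and-fire membranes with current-based exponential
synapses are advanced with the exact exponential propagator of the
linear (V, g_e, g_i) system at a fixed step (default dt = 0.1 ms);
threshold, reset and refractoriness are applied after each propagation
and spikes are delivered to their targets within the same step (zero
transmission delay).  The default drive is a constant depolarization of
11 mV per cell (relaxation target E_L + 11 mV); a per-cell external
Poisson drive of matched mean current is available as an alternative.

The heavy lifting happens in :mod:`drivernet._kernel` (numba); this
module owns the user-facing state containers and orchestration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernel
from .plasticity import PlasticityConfig, STDPParams
from .topology import NeuronParams, SynapseParams, Topology

__all__ = [
    "NetworkState",
    "DriveSpec",
    "StimulusSpec",
    "SpikeRecord",
    "SimResult",
    "DivergenceError",
    "psp_peak_amplitude",
    "step_network",
    "run_simulation",
    "apply_stimulus_protocol",
]

DEFAULT_DT = 0.1  # ms


class DivergenceError(RuntimeError):
    """Raised when the population rate exceeds the configured ceiling or
    the state becomes non-finite."""


@dataclass
class NetworkState:
    """Dynamical state of all cells at simulation time ``t`` (ms)."""

    V: np.ndarray                    # membrane potentials (mV)
    g_e: np.ndarray                  # excitatory synaptic traces
    g_i: np.ndarray                  # inhibitory synaptic traces
    refractory_remaining: np.ndarray  # time left clamped at V_reset (ms)
    t: float = 0.0

    @classmethod
    def initial(cls, n: int, neuron: NeuronParams = NeuronParams(),
                seed: int = 0) -> "NetworkState":
        """Fresh state with V ~ Uniform[V_reset, V_thres), zero traces."""
        rng = np.random.default_rng(seed)
        V = rng.uniform(neuron.V_reset, neuron.V_thres, size=n)
        return cls(V, np.zeros(n), np.zeros(n), np.zeros(n), 0.0)

    def copy(self) -> "NetworkState":
        return NetworkState(self.V.copy(), self.g_e.copy(), self.g_i.copy(),
                            self.refractory_remaining.copy(), self.t)


@dataclass(frozen=True)
class DriveSpec:
    """External drive: constant depolarization (mV above E_L) or an
    equivalent per-cell Poisson spike train through a unit-weight
    excitatory synapse (rate = depolarization / (c_e tau_e))."""

    mode: str = "constant"
    depolarization: float = 11.0     # mV, constant mode
    rate: float | None = None        # Hz per cell, poisson mode
    unit_weight: float = 1.0         # weight of external events

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "poisson"):
            raise ValueError("mode must be 'constant' or 'poisson'")
        if self.depolarization < 0:
            raise ValueError("depolarization must be non-negative")
        if self.rate is not None and self.rate < 0:
            raise ValueError("poisson rate must be non-negative")

    def poisson_rate(self, synapse: SynapseParams) -> float:
        """Per-cell external event rate (Hz) matching the constant drive's
        mean current if no explicit rate was given."""
        if self.rate is not None:
            return self.rate
        # mean current of rate r through unit weight: c_e * r * tau_e
        return self.depolarization / (
            synapse.c_e_norm * self.unit_weight * synapse.tau_e / 1000.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Brief very strong current pulses forcing a cell group to spike.

    ``inter_pulse_gap`` is the separation between successive pulse
    *onsets*; with the default 2 ms (the refractory period) every
    stimulated cell has left refractoriness when the next pulse arrives,
    so its spikes are 2 + epsilon ms apart with epsilon of order dt.
    """

    target_ids: tuple = ()
    pulse_duration: float = 0.5   # ms
    inter_pulse_gap: float = 2.0  # ms, onset-to-onset
    amplitude: float = 3000.0     # mV-equivalent drive
    n_pulses: int = 2

    def __post_init__(self) -> None:
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.n_pulses > 1 and self.inter_pulse_gap <= 0:
            raise ValueError("inter_pulse_gap must be positive")


class SpikeRecord:
    """Time-stamped spike list: parallel arrays of times (ms) and ids.

    Times are non-decreasing; per-neuron inter-spike intervals respect
    the refractory period by construction.
    """

    def __init__(self, times, ids, n_e: int, n_i: int, duration: float):
        self.times = np.asarray(times, dtype=np.float64)
        self.ids = np.asarray(ids, dtype=np.int64)
        if self.times.shape != self.ids.shape:
            raise ValueError("times and ids must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")
        self.n_e = int(n_e)
        self.n_i = int(n_i)
        self.duration = float(duration)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def by_neuron(self) -> list[np.ndarray]:
        """Per-neuron spike-time arrays (single sort, O(S log S))."""
        order = np.lexsort((self.times, self.ids))
        ids = self.ids[order]
        times = self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_total + 1))
        return [times[bounds[k]:bounds[k + 1]] for k in range(self.n_total)]

    def window(self, t0: float, t1: float) -> "SpikeRecord":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRecord(self.times[m], self.ids[m], self.n_e, self.n_i,
                           t1 - t0)

    def excitatory(self) -> "SpikeRecord":
        m = self.ids < self.n_e
        return SpikeRecord(self.times[m], self.ids[m], self.n_e, self.n_i,
                           self.duration)

    @staticmethod
    def concatenate(records: list["SpikeRecord"], duration: float) -> "SpikeRecord":
        if not records:
            raise ValueError("need at least one record")
        times = np.concatenate([r.times for r in records])
        ids = np.concatenate([r.ids for r in records])
        r0 = records[0]
        return SpikeRecord(times, ids, r0.n_e, r0.n_i, duration)


@dataclass
class SimResult:
    spikes: SpikeRecord
    topology: Topology
    state: NetworkState
    #: (t_ms, class -> (mean, var)) sampled at snapshot boundaries
    weight_trajectory: list = field(default_factory=list)
    #: (t_ms, copy of E-E weight data) if full snapshots were requested
    ee_snapshots: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# closed-form PSP calibration
# ---------------------------------------------------------------------------

def psp_peak_amplitude(kind: str, w: float,
                       neuron: NeuronParams = NeuronParams(),
                       synapse: SynapseParams = SynapseParams()) -> float:
    """Peak membrane deflection caused by one presynaptic spike.

    The response to a single spike through an exponential current synapse
    is dV(t) = w |c| (tau_s/(tau_m - tau_s)) (exp(-t/tau_m) - exp(-t/tau_s)),
    peaking at t* = tau_m tau_s/(tau_m - tau_s) * ln(tau_m/tau_s).  For the
    base parameters the unit-weight peaks are +0.157 mV (excitatory) and
    -2.25 mV (inhibitory).  Negative sign for inhibitory synapses.
    """
    if w < 0:
        raise ValueError("weight must be non-negative")
    if kind == "excitatory":
        tau_s, c = synapse.tau_e, abs(synapse.c_e_norm)
        sign = 1.0
    elif kind == "inhibitory":
        tau_s, c = synapse.tau_i, abs(synapse.c_i_norm)
        sign = -1.0
    else:
        raise ValueError("kind must be 'excitatory' or 'inhibitory'")
    tau_m = neuron.tau_m
    if math.isclose(tau_s, tau_m):
        # degenerate limit: dV(t) = w c (t/tau_m) exp(-t/tau_m), peak at tau_m
        peak = w * c * math.exp(-1.0)
    else:
        t_star = tau_m * tau_s / (tau_m - tau_s) * math.log(tau_m / tau_s)
        peak = (w * c * tau_s / (tau_m - tau_s)
                * (math.exp(-t_star / tau_m) - math.exp(-t_star / tau_s)))
    return sign * peak


# ---------------------------------------------------------------------------
# kernel plumbing
# ---------------------------------------------------------------------------

class _SimContext:
    """Prepared flat arrays binding a topology to the numba kernel.

    Weight data is shared with the kernel; ``export_topology`` splits the
    (possibly plasticity-modified) combined matrices back into the four
    connection classes.
    """

    def __init__(self, topology: Topology, neuron: NeuronParams,
                 synapse: SynapseParams, plasticity: PlasticityConfig | None,
                 dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.topology_shape = (topology.n_e, topology.n_i)
        self.neuron = neuron
        self.synapse = synapse
        self.dt = dt
        n_e, n_i = topology.n_e, topology.n_i

        exc = sp.hstack([topology.w["ee"], topology.w["ei"]]).tocsr()
        inh = sp.hstack([topology.w["ie"], topology.w["ii"]]).tocsr()
        exc.sort_indices()
        inh.sort_indices()
        self.exc_indptr = exc.indptr.astype(np.int64)
        self.exc_indices = exc.indices.astype(np.int64)
        self.exc_data = exc.data.astype(np.float64)
        self.inh_indptr = inh.indptr.astype(np.int64)
        self.inh_indices = inh.indices.astype(np.int64)
        self.inh_data = inh.data.astype(np.float64)

        self.ee_cptr, self.ee_cpos, self.ee_crow = self._csc_view(
            self.exc_indptr, self.exc_indices, n_e, n_e)
        self.ie_cptr, self.ie_cpos, self.ie_crow = self._csc_view(
            self.inh_indptr, self.inh_indices, n_i, n_e)

        # exact propagator constants
        tm, te, ti = neuron.tau_m, synapse.tau_e, synapse.tau_i
        self.a_m = math.exp(-dt / tm)
        self.a_e = math.exp(-dt / te)
        self.a_i = math.exp(-dt / ti)
        self.k_e = abs(synapse.c_e_norm) * te / (tm - te) * (self.a_m - self.a_e)
        self.k_i = abs(synapse.c_i_norm) * ti / (tm - ti) * (self.a_m - self.a_i)
        self.ref_steps = int(math.ceil(neuron.tau_ref / dt))

        # plasticity configuration
        pc = plasticity
        self.ee_on = pc is not None and pc.ee_stdp is not None
        self.ie_on = pc is not None and pc.ie_stdp is not None
        self.norm_on = pc is not None and pc.normalization is not None
        self.scal_on = pc is not None and pc.scaling is not None

        def eff(p: STDPParams, plus: bool) -> float:
            scale = p.w_max if p.effective_scaling else 1.0
            return (p.A_plus if plus else p.A_minus) * scale

        if self.ee_on:
            p = pc.ee_stdp
            self.ee_mode = {"additive": _kernel.MODE_ADDITIVE,
                            "partly_multiplicative": _kernel.MODE_PARTLY,
                            "fully_multiplicative": _kernel.MODE_FULLY}[p.mode]
            self.ee_ap, self.ee_am = eff(p, True), eff(p, False)
            self.ee_dec_p = math.exp(-dt / p.tau_plus)
            self.ee_dec_m = math.exp(-dt / p.tau_minus)
            self.ee_wmax = p.w_max
        else:
            self.ee_mode, self.ee_ap, self.ee_am = 0, 0.0, 0.0
            self.ee_dec_p = self.ee_dec_m = 1.0
            self.ee_wmax = synapse.w_e_max
        if self.ie_on:
            p = pc.ie_stdp
            if p.mode != "additive":
                raise ValueError("inhibitory STDP is additive only")
            self.ie_ap, self.ie_am = eff(p, True), eff(p, False)
            self.ie_dec_p = math.exp(-dt / p.tau_plus)
            self.ie_dec_m = math.exp(-dt / p.tau_minus)
            self.ie_wmax = p.w_max
        else:
            self.ie_ap = self.ie_am = 0.0
            self.ie_dec_p = self.ie_dec_m = 1.0
            self.ie_wmax = synapse.w_i_max

        self.x_pre = np.zeros(n_e)
        self.x_post = np.zeros(n_e)
        self.y_pre = np.zeros(n_i)
        self.y_post = np.zeros(n_e)
        # last-update global steps of the lazily decayed traces
        self.lx_pre = np.zeros(n_e, dtype=np.int64)
        self.lx_post = np.zeros(n_e, dtype=np.int64)
        self.ly_pre = np.zeros(n_i, dtype=np.int64)
        self.ly_post = np.zeros(n_e, dtype=np.int64)

        if self.norm_on:
            self.norm_every = max(1, int(round(pc.normalization.interval / dt)))
            deg = np.diff(self.ee_cptr).astype(np.float64)
            self.ee_target_sum = deg * pc.normalization.target_mean
        else:
            self.norm_every = 1
            self.ee_target_sum = np.zeros(n_e)

        if self.scal_on:
            s = pc.scaling
            self.scal_every = max(1, int(round(s.step_interval / dt)))
            self.bin_seconds = self.scal_every * dt / 1000.0
            self.window_bins = max(1, int(round(
                s.rate_window / self.bin_seconds)))
            self.gamma, self.nu0 = s.gamma, s.nu_0
        else:
            self.scal_every = 1
            self.bin_seconds = 1.0
            self.window_bins = 1
            self.gamma, self.nu0 = 0.0, 0.0
        self.cur_counts = np.zeros(n_e, dtype=np.int64)
        self.rate_counts = np.zeros(
            (self.window_bins if self.scal_on else 1, n_e), dtype=np.int64)
        self.rate_totals = np.zeros(n_e)
        self.rate_state = np.zeros(2, dtype=np.int64)

    @staticmethod
    def _csc_view(indptr, indices, n_rows, n_e):
        """Column-compressed view of the E-targeted entries of a CSR
        matrix: (cptr, positions-into-data, presynaptic-row-ids)."""
        rows = np.repeat(np.arange(n_rows, dtype=np.int64),
                         np.diff(indptr))
        pos = np.arange(indices.size, dtype=np.int64)
        m = indices < n_e
        cols, rows, pos = indices[m], rows[m], pos[m]
        order = np.argsort(cols, kind="stable")
        cols, rows, pos = cols[order], rows[order], pos[order]
        cptr = np.searchsorted(cols, np.arange(n_e + 1)).astype(np.int64)
        return cptr, pos, rows

    def run(self, state: NetworkState, drive_vec: np.ndarray, n_steps: int,
            step0: int, poisson_lam_total: float, poisson_w: float,
            record_from: int, spike_cap: int):
        spike_step = np.empty(spike_cap, dtype=np.int64)
        spike_id = np.empty(spike_cap, dtype=np.int64)
        ref = np.round(state.refractory_remaining / self.dt).astype(np.int64)
        n_rec, total, ok = _kernel.run_steps(
            self.topology_shape[0], self.topology_shape[1], n_steps, step0,
            self.a_m, self.a_e, self.a_i, self.k_e, self.k_i,
            self.neuron.E_L, self.neuron.V_thres, self.neuron.V_reset,
            self.ref_steps,
            state.V, state.g_e, state.g_i, ref,
            drive_vec, poisson_lam_total, poisson_w,
            self.exc_indptr, self.exc_indices, self.exc_data,
            self.inh_indptr, self.inh_indices, self.inh_data,
            self.ee_on, self.ee_mode, self.ee_ap, self.ee_am, self.ee_wmax,
            self.ee_dec_p, self.ee_dec_m,
            self.x_pre, self.x_post, self.lx_pre, self.lx_post,
            self.ee_cptr, self.ee_cpos, self.ee_crow,
            self.ie_on, self.ie_ap, self.ie_am, self.ie_wmax,
            self.ie_dec_p, self.ie_dec_m,
            self.y_pre, self.y_post, self.ly_pre, self.ly_post,
            self.ie_cptr, self.ie_cpos, self.ie_crow,
            self.norm_on, self.norm_every, self.ee_target_sum,
            self.scal_on, self.scal_every, self.gamma, self.nu0,
            self.bin_seconds, self.window_bins,
            self.cur_counts, self.rate_counts, self.rate_totals,
            self.rate_state,
            record_from, spike_step, spike_id,
        )
        state.refractory_remaining = ref.astype(np.float64) * self.dt
        state.t += n_steps * self.dt
        if ok == -1:
            raise DivergenceError("non-finite membrane potential encountered")
        return spike_step[:n_rec], spike_id[:n_rec], total, ok == 1

    # weight bookkeeping -----------------------------------------------------
    def class_masks(self):
        n_e, n_i = self.topology_shape
        return {
            "ee": self.exc_indices < n_e,
            "ei": self.exc_indices >= n_e,
            "ie": self.inh_indices < n_e,
            "ii": self.inh_indices >= n_e,
        }

    def ee_weights(self) -> np.ndarray:
        return self.exc_data[self.exc_indices < self.topology_shape[0]]

    def weight_stats(self):
        masks = self.class_masks()
        out = {}
        for cls in ("ee", "ei"):
            d = self.exc_data[masks[cls]]
            out[cls] = (float(d.mean()), float(d.var())) if d.size else (0.0, 0.0)
        for cls in ("ie", "ii"):
            d = self.inh_data[masks[cls]]
            out[cls] = (float(d.mean()), float(d.var())) if d.size else (0.0, 0.0)
        return out

    def export_topology(self, positions=None) -> Topology:
        n_e, n_i = self.topology_shape

        def split(indptr, indices, data, n_rows):
            # manual split by target class: keeps synapses whose weight
            # plasticity drove to exactly zero (structural edges)
            rows = np.repeat(np.arange(n_rows, dtype=np.int64),
                             np.diff(indptr))
            left = indices < n_e
            a = sp.csr_matrix(
                (data[left].copy(), (rows[left], indices[left])),
                shape=(n_rows, n_e))
            b = sp.csr_matrix(
                (data[~left].copy(), (rows[~left], indices[~left] - n_e)),
                shape=(n_rows, n_i))
            return a, b

        ee, ei = split(self.exc_indptr, self.exc_indices, self.exc_data, n_e)
        ie, ii = split(self.inh_indptr, self.inh_indices, self.inh_data, n_i)
        return Topology(n_e, n_i, {"ee": ee, "ei": ei, "ie": ie, "ii": ii},
                        positions=positions)


def _drive_vector(topology: Topology, drive: DriveSpec) -> np.ndarray:
    n = topology.n_total
    if drive.mode == "constant":
        return np.full(n, drive.depolarization, dtype=np.float64)
    return np.zeros(n, dtype=np.float64)


def _poisson_args(topology: Topology, drive: DriveSpec,
                  synapse: SynapseParams, dt: float):
    if drive.mode != "poisson":
        return 0.0, 0.0
    rate = drive.poisson_rate(synapse)
    lam_total = topology.n_total * rate * dt / 1000.0
    return lam_total, drive.unit_weight


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def step_network(state: NetworkState, topology: Topology,
                 drive: DriveSpec = DriveSpec(), dt: float = DEFAULT_DT,
                 neuron: NeuronParams = NeuronParams(),
                 synapse: SynapseParams = SynapseParams(),
                 plasticity: PlasticityConfig | None = None,
                 _context: _SimContext | None = None):
    """Advance the network one step of length dt.

    Returns (state, spiking ids this step).  Convenience wrapper over the
    kernel for inspection and tests; long runs should use
    :func:`run_simulation`.  Pass ``_context`` to reuse prepared arrays
    (weight changes then accumulate in the context).
    """
    if not np.all(np.isfinite(state.V)):
        raise DivergenceError("non-finite membrane potential in input state")
    ctx = _context or _SimContext(topology, neuron, synapse, plasticity, dt)
    drive_vec = _drive_vector(topology, drive)
    lam, pw = _poisson_args(topology, drive, synapse, dt)
    step0 = int(round(state.t / dt))
    steps, ids, _, _ = ctx.run(state, drive_vec, 1, step0, lam, pw,
                               record_from=0, spike_cap=topology.n_total)
    return state, ids


def run_simulation(topology: Topology, drive: DriveSpec = DriveSpec(),
                   duration: float = 1000.0, dt: float = DEFAULT_DT,
                   plasticity: PlasticityConfig | None = None,
                   neuron: NeuronParams = NeuronParams(),
                   synapse: SynapseParams = SynapseParams(),
                   seed: int = 0,
                   initial_state: NetworkState | None = None,
                   record_spikes: bool = True,
                   record_from: float = 0.0,
                   snapshot_interval: float | None = None,
                   snapshot_full: bool = False,
                   rate_ceiling: float = 100.0,
                   spike_buffer_rate: float = 120.0,
                   chunk_duration: float = 10_000.0) -> SimResult:
    """Simulate the network for ``duration`` ms.

    Initial membrane potentials are drawn Uniform[V_reset, V_thres) unless
    an ``initial_state`` is given.  Spike times in the returned record are
    relative to the start of this run (the state clock keeps absolute
    time).  ``record_from`` discards spikes before that time (ms).  ``snapshot_interval`` (ms) samples per-class weight
    means/variances (and full E-E weight copies if ``snapshot_full``).
    A mean population rate above ``rate_ceiling`` Hz sustained over a
    10 s chunk aborts with :class:`DivergenceError`.  Bit-reproducible
    for a given seed.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    n = topology.n_total
    ctx = _SimContext(topology, neuron, synapse, plasticity, dt)
    ss = np.random.SeedSequence(seed)
    init_seed, kern_seed = ss.generate_state(2)
    state = (initial_state.copy() if initial_state is not None
             else NetworkState.initial(n, neuron, seed=int(init_seed)))
    _kernel.seed_rng(int(kern_seed) % (2 ** 31))

    drive_vec = _drive_vector(topology, drive)
    lam, pw = _poisson_args(topology, drive, synapse, dt)

    n_steps = int(round(duration / dt))
    chunk_steps = max(1, int(round(chunk_duration / dt)))
    record_from_step = int(round(record_from / dt))
    snap_steps = (int(round(snapshot_interval / dt))
                  if snapshot_interval else None)

    t0_step = int(round(state.t / dt))
    trajectory = []
    ee_snaps = []
    seg_times, seg_ids = [], []
    truncated = False

    def take_snapshot(step):
        t_ms = step * dt
        trajectory.append((t_ms, ctx.weight_stats()))
        if snapshot_full:
            ee_snaps.append((t_ms, ctx.ee_weights().copy()))

    if snap_steps:
        take_snapshot(t0_step)

    done = 0
    next_snap = snap_steps if snap_steps else None
    while done < n_steps:
        todo = min(chunk_steps, n_steps - done)
        if next_snap is not None:
            todo = min(todo, next_snap - done)
        rec_from = max(0, record_from_step - done) if record_spikes else todo
        cap = (int(n * todo * dt / 1000.0 * spike_buffer_rate) + 64
               if record_spikes and rec_from < todo else 1)
        steps, ids, total, rec_ok = ctx.run(
            state, drive_vec, todo, t0_step + done, lam, pw, rec_from, cap)
        if steps.size:
            # spike times relative to the start of this run
            seg_times.append((steps - t0_step).astype(np.float64) * dt)
            seg_ids.append(ids)
        if not rec_ok:
            truncated = True
        done += todo
        mean_rate = total / (n * todo * dt / 1000.0)
        if mean_rate > rate_ceiling and todo * dt >= 10_000.0 - 1e-9:
            raise DivergenceError(
                f"mean population rate {mean_rate:.1f} Hz exceeded the "
                f"ceiling of {rate_ceiling} Hz over a {todo * dt / 1000:.0f} s window")
        if next_snap is not None and done == next_snap:
            take_snapshot(t0_step + done)
            next_snap += snap_steps
    if truncated:
        raise DivergenceError(
            "spike recording buffer overflow (population rate far above the "
            "expected regime); raise spike_buffer_rate or the rate ceiling")

    times = (np.concatenate(seg_times) if seg_times
             else np.empty(0, dtype=np.float64))
    ids = np.concatenate(seg_ids) if seg_ids else np.empty(0, dtype=np.int64)
    spikes = SpikeRecord(times, ids, topology.n_e, topology.n_i, duration)
    final = ctx.export_topology(positions=None if topology.positions is None
                                else topology.positions.copy())
    return SimResult(spikes, final, state, trajectory, ee_snaps)


def apply_stimulus_protocol(state: NetworkState, topology: Topology,
                            stimulus: StimulusSpec, dt: float = DEFAULT_DT,
                            drive: DriveSpec = DriveSpec(),
                            neuron: NeuronParams = NeuronParams(),
                            synapse: SynapseParams = SynapseParams()):
    """Force a cell group to fire ``n_pulses`` spikes with brief strong
    current pulses while the rest of the network runs freely.

    The protocol only proceeds when no targeted cell is refractory at
    onset; otherwise returns ``success=False`` with the state unchanged.
    Plasticity is frozen during stimulation.  Returns
    (state, SpikeRecord over the protocol window, success).
    """
    targets = np.asarray(list(stimulus.target_ids), dtype=np.int64)
    n = topology.n_total
    if targets.size and (targets.min() < 0 or targets.max() >= n):
        raise ValueError("unknown target ids")
    empty = SpikeRecord(np.empty(0), np.empty(0, dtype=np.int64),
                        topology.n_e, topology.n_i, 0.0)
    if targets.size == 0:
        return state, empty, True
    if np.any(state.refractory_remaining[targets] > 0):
        return state, empty, False
    # the pulse must force a crossing within a single step from reset
    step_gain = (1.0 - math.exp(-dt / neuron.tau_m))
    if (stimulus.amplitude + neuron.E_L - neuron.V_reset) * step_gain < (
            neuron.V_thres - neuron.V_reset):
        raise ValueError("stimulus amplitude too weak to force a spike "
                         "within one step")

    ctx = _SimContext(topology, neuron, synapse, None, dt)
    base = _drive_vector(topology, drive)
    lam, pw = _poisson_args(topology, drive, synapse, dt)
    pulse_steps = max(1, int(round(stimulus.pulse_duration / dt)))
    onset_steps = max(pulse_steps, int(round(stimulus.inter_pulse_gap / dt)))

    seg_times, seg_ids = [], []
    t_begin = state.t
    step0 = int(round(t_begin / dt))
    done = 0

    def advance(n_steps, drive_vec):
        nonlocal done
        if n_steps <= 0:
            return
        cap = n * n_steps + 64
        steps, ids, _, _ = ctx.run(state, drive_vec, n_steps, step0 + done,
                                   lam, pw, 0, cap)
        if steps.size:
            seg_times.append(steps.astype(np.float64) * dt)
            seg_ids.append(ids)
        done += n_steps

    pulsed = base.copy()
    pulsed[targets] += stimulus.amplitude
    for k in range(stimulus.n_pulses):
        advance(pulse_steps, pulsed)
        if k < stimulus.n_pulses - 1:
            advance(onset_steps - pulse_steps, base)

    times = (np.concatenate(seg_times) - step0 * dt if seg_times
             else np.empty(0))
    ids = np.concatenate(seg_ids) if seg_ids else np.empty(0, dtype=np.int64)
    rec = SpikeRecord(times, ids, topology.n_e, topology.n_i, done * dt)
    ok = all(np.sum(rec.ids == t) == stimulus.n_pulses for t in targets)
    return state, rec, ok
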