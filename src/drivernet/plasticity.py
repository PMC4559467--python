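"""Synaptic plasticity rules.

Three mechanisms act together in the full model:

* **Excitatory STDP** at E-E synapses: all-to-all pair-based Hebbian rule
  with exponential kernels (tau_+ = tau_- = 20 ms), amplitudes
  A_+ = 1e-3, A_- = 1.05 A_+ (depression slightly dominates).  For
  additive rules the amplitudes are multiplied by the class maximal
  weight to obtain their effective values.
* **Inhibitory STDP** at I-E synapses: same Hebbian kernel with
  A_- = 1e-3, A_+ = 4 A_- (the kernel integral is positive, so
  inhibition onto fast-firing cells is up-regulated).
* **Homeostasis** at the postsynaptic site of E-E synapses: either a
  hard weight normalization every 100 ms (each excitatory cell's
  incoming E-E weights are rescaled so their mean is exactly the target,
  default 1), or a slow synaptic-scaling ODE dw/dt = -gamma (nu - nu0) w^2
  applied every 50 ms with the rate estimated over a 100 s sliding window.

The online trace realization (one presynaptic and one postsynaptic
eligibility trace per cell) is exactly equivalent to summing the kernel
over all spike pairs; :func:`stdp_weight_change` implements it
event-driven and the simulation engine implements the same algebra on
the dt grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "STDPParams",
    "EE_STDP",
    "IE_STDP",
    "NormalizationParams",
    "ScalingParams",
    "PlasticityConfig",
    "TraceState",
    "pair_delta_w",
    "stdp_on_pre",
    "stdp_on_post",
    "stdp_weight_change",
    "normalize_incoming",
    "scaling_step",
]

_MODES = ("additive", "partly_multiplicative", "fully_multiplicative")


@dataclass(frozen=True)
class STDPParams:
    """Pair-based STDP kernel parameters.

    ``mode`` selects the weight dependence of the amplitudes:

    - ``additive``: A+(w) = A+, A-(w) = A- (constants);
    - ``partly_multiplicative``: additive potentiation, depression
      proportional to the current weight, A-(w) = A- * w;
    - ``fully_multiplicative``: A+(w) = A+ * (w_max - w),
      A-(w) = A- * w.

    With ``effective_scaling`` the additive amplitude constants are
    pre-multiplied by ``w_max`` ("multiplied with the respective maximal
    weight"), so the effective additive E-E amplitudes are 0.02 / 0.021.
    """

    A_plus: float
    A_minus: float
    tau_plus: float = 20.0   # ms
    tau_minus: float = 20.0  # ms
    mode: str = "additive"
    w_max: float = 20.0
    effective_scaling: bool = True

    def __post_init__(self) -> None:
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")

    # amplitude functions -------------------------------------------------
    def amp_plus(self, w: float) -> float:
        scale = self.w_max if self.effective_scaling else 1.0
        if self.mode == "fully_multiplicative":
            return self.A_plus * scale * max(0.0, 1.0 - w / self.w_max)
        return self.A_plus * scale

    def amp_minus(self, w: float) -> float:
        scale = self.w_max if self.effective_scaling else 1.0
        if self.mode in ("partly_multiplicative", "fully_multiplicative"):
            return self.A_minus * scale * (w / self.w_max)
        return self.A_minus * scale


def EE_STDP(**kw) -> STDPParams:
    """Base-model excitatory STDP (A+ = 1e-3, A- = 1.05e-3, w_max = 20)."""
    args = dict(A_plus=1e-3, A_minus=1.05e-3, w_max=20.0)
    args.update(kw)
    return STDPParams(**args)


def IE_STDP(**kw) -> STDPParams:
    """Base-model inhibitory STDP (A- = 1e-3, A+ = 4e-3, w_max = 5)."""
    args = dict(A_plus=4e-3, A_minus=1e-3, w_max=5.0)
    args.update(kw)
    return STDPParams(**args)


@dataclass(frozen=True)
class NormalizationParams:
    """Hard incoming-weight normalization (synaptic scaling, fast form)."""

    interval: float = 100.0    # ms between normalization passes
    target_mean: float = 1.0   # target mean incoming weight

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")


@dataclass(frozen=True)
class ScalingParams:
    """Slow multiplicative synaptic scaling dw/dt = -gamma (nu - nu0) w^2."""

    gamma: float = 1e-6        # 1/(Hz s) in weight units
    nu_0: float = 0.0          # target rate (Hz)
    step_interval: float = 50.0  # ms between scaling steps
    rate_window: float = 100.0   # s, sliding window of the rate estimate

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.rate_window <= 0:
            raise ValueError("rate_window must be positive")


@dataclass
class PlasticityConfig:
    """Which rules are active during a plastic run.

    Any of the three components may be ``None`` (disabled).  The base
    model uses all defaults: additive E-E STDP, additive I-E STDP and the
    100 ms normalization; ``scaling`` replaces ``normalization`` in the
    slow-homeostasis variant.
    """

    ee_stdp: STDPParams | None = field(default_factory=EE_STDP)
    ie_stdp: STDPParams | None = field(default_factory=IE_STDP)
    normalization: NormalizationParams | None = field(default_factory=NormalizationParams)
    scaling: ScalingParams | None = None

    def __post_init__(self) -> None:
        if self.normalization is not None and self.scaling is not None:
            raise ValueError("enable either normalization or slow scaling, not both")


@dataclass
class TraceState:
    """Per-cell eligibility traces of the online all-to-all realization.

    ``x_pre[i]`` sums exp(-(t - t_pre)/tau_plus) over past presynaptic
    spikes of cell i; ``x_post[j]`` the analogue with tau_minus over
    postsynaptic spikes.
    """

    x_pre: np.ndarray
    x_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "TraceState":
        return cls(np.zeros(n_pre), np.zeros(n_post))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def pair_delta_w(delta_t: float, w: float, params: STDPParams) -> float:
    """Weight change of a single spike pair, delta_t = t_post - t_pre (ms).

    delta_t > 0 is potentiating; delta_t <= 0 (including coincidence)
    falls into the depression branch.
    """
    if delta_t > 0:
        return params.amp_plus(w) * np.exp(-delta_t / params.tau_plus)
    return -params.amp_minus(w) * np.exp(delta_t / params.tau_minus)


def stdp_on_pre(w: float, x_post_value: float, params: STDPParams) -> float:
    """Depression applied when the presynaptic cell fires.

    ``x_post_value`` is the postsynaptic trace at the presynaptic spike
    time (including a same-instant postsynaptic spike, which belongs to
    the depression branch).  Returns the clipped new weight; the caller
    increments the presynaptic trace by 1 afterwards.
    """
    w = w - params.amp_minus(w) * x_post_value
    return min(max(w, 0.0), params.w_max)


def stdp_on_post(w: float, x_pre_value: float, params: STDPParams) -> float:
    """Potentiation applied when the postsynaptic cell fires (mirror of
    :func:`stdp_on_pre`; ``x_pre_value`` must exclude a same-instant
    presynaptic spike)."""
    w = w + params.amp_plus(w) * x_pre_value
    return min(max(w, 0.0), params.w_max)


def stdp_weight_change(pre_times, post_times, w0: float, params: STDPParams,
                       clip: bool = True) -> float:
    """Event-driven trace evaluation of the all-to-all pair rule on one
    synapse given full spike trains (times in ms).

    Processes events in time order; at coincident pre/post events the
    depression-on-pre update sees the simultaneous postsynaptic spike
    (delta_t = 0 pairs depress) while the potentiation-on-post update
    does not see the simultaneous presynaptic spike.
    """
    events = sorted(
        [(float(t), 0) for t in pre_times] + [(float(t), 1) for t in post_times])
    w = float(w0)
    x_pre = x_post = 0.0
    t_last = None
    i = 0
    while i < len(events):
        t = events[i][0]
        if t_last is not None:
            dt = t - t_last
            x_pre *= np.exp(-dt / params.tau_plus)
            x_post *= np.exp(-dt / params.tau_minus)
        n_pre = n_post = 0
        while i < len(events) and events[i][0] == t:
            if events[i][1] == 0:
                n_pre += 1
            else:
                n_post += 1
            i += 1
        x_post += n_post
        for _ in range(n_pre):
            w = w - params.amp_minus(w) * x_post
            if clip:
                w = min(max(w, 0.0), params.w_max)
        for _ in range(n_post):
            w = w + params.amp_plus(w) * x_pre
            if clip:
                w = min(max(w, 0.0), params.w_max)
        x_pre += n_pre
        t_last = t
    return w


_warned_zero_sum = False


def normalize_incoming(weights_in: np.ndarray, in_degree: int,
                       target_mean: float = 1.0) -> np.ndarray:
    """Rescale one cell's incoming E-E weight vector so that its sum is
    exactly ``in_degree * target_mean`` (mean pinned at the target while
    relative proportions are preserved).

    An all-zero vector cannot be rescaled and is returned unchanged with
    a warning (emitted once per process).
    """
    global _warned_zero_sum
    w = np.asarray(weights_in, dtype=float)
    if w.size == 0 or in_degree != w.size:
        raise ValueError("in_degree must equal the number of incoming weights (> 0)")
    s = w.sum()
    if s <= 0.0:
        if not _warned_zero_sum:
            warnings.warn("normalization skipped for a cell with zero incoming "
                          "weight sum", RuntimeWarning, stacklevel=2)
            _warned_zero_sum = True
        return w.copy()
    return w * (in_degree * target_mean / s)


def scaling_step(w, nu, params: ScalingParams, dt_step: float | None = None,
                 w_max: float = np.inf):
    """One Euler step of the scaling ODE: w <- w - gamma (nu - nu0) w^2 dt.

    ``dt_step`` is the elapsed time in seconds (defaults to the configured
    step interval).  Broadcasts over arrays; result clipped to [0, w_max].
    """
    if np.any(np.asarray(nu) < 0):
        raise ValueError("rates must be non-negative")
    if dt_step is None:
        dt_step = params.step_interval / 1000.0
    w = np.asarray(w, dtype=float)
    out = w - params.gamma * (np.asarray(nu) - params.nu_0) * w * w * dt_step
    out = np.clip(out, 0.0, w_max)
    return float(out) if out.ndim == 0 else out
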