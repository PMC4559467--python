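"""Mean-field theory of STDP in reduced two-neuron models.

Two closed-form strands, both for delta-synapse reduced models in which
weights carry units of mV (the network's dimensionless weights convert
through the unit-PSP calibration; the conversion is always explicit):

* **Inhibitory STDP**: a presynaptic inhibitory spike of strength w
  delays the postsynaptic spike by d = w / (nu0 (V_thres - V_rest)) for
  a cell that would fire at nu0 without the synapse.  Averaging the
  nearest-neighbour pair rule over the ISI gives a stationary weight
  w_stat = nu0 tau (V_thres - V_rest) ln(A+/A-) and a compensated
  postsynaptic rate nu = nu0 / (1 + tau nu_inh ln(A+/A-)): inhibition
  partially, never fully, compensates extra drive.

* **Excitatory STDP**: the average weight change per presynaptic spike
  follows from spike triplets (one presynaptic spike inside one
  postsynaptic ISI), the backward shift of the next postsynaptic spike,
  the inverse-Gaussian ISI distribution of a Poisson-driven LIF cell,
  and the probability that a presynaptic spike directly triggers a
  postsynaptic one.  Depression dominates at w = 0; the direct-trigger
  and shift terms make the mean update positive above a threshold
  weight - the instability that lets strong synapses run away (up to
  homeostatic control) and drivers emerge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "TheoryParams",
    "MembraneDistribution",
    "inhibitory_delay",
    "stationary_inhibitory_weight",
    "mean_inhibitory_update",
    "rate_with_inhibition",
    "pair_contribution",
    "postsynaptic_shift",
    "fire_probability",
    "membrane_distribution",
    "diffusion_membrane_density",
    "expected_weight_change",
    "fit_rate_slope",
]


@dataclass(frozen=True)
class TheoryParams:
    """Parameters of the reduced mean-field models.

    Amplitudes are effective (already scaled by the maximal weight where
    the additive convention calls for it); times in ms unless suffixed,
    rates in Hz.  ``delta_r_slope`` (Hz per mV of synaptic weight) is
    always fitted from a simulation sweep, never derived.
    """

    tau: float = 20.0            # STDP time constant (ms), tau_+ = tau_-
    A_plus: float = 0.02         # effective potentiation amplitude
    A_minus: float = 0.005       # effective depression amplitude (inhibitory strand)
    V_thres: float = -50.0       # mV
    V_rest: float = -60.0        # mV
    nu_0: float = 5.0            # base postsynaptic rate (Hz)
    nu_inh: float = 5.0          # inhibitory presynaptic rate (Hz)
    tau_syn: float = 0.1         # synaptic delay (ms); engine dt by default
    nu: float = 5.0              # postsynaptic rate of the excitatory pair (Hz)
    lam: float | None = None     # inverse-Gaussian lambda (s); default 0.75/nu
    delta_r_slope: float = 0.0   # Hz per mV, fitted

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.V_thres <= self.V_rest:
            raise ValueError("V_thres must exceed V_rest")

    @classmethod
    def inhibitory(cls, **kw) -> "TheoryParams":
        """Inhibitory-STDP strand: effective amplitudes A+ = 4 A- with
        A- = 1e-3 * w_i_max = 0.005 (the ratio ln 4 is what matters)."""
        args = dict(A_plus=0.02, A_minus=0.005)
        args.update(kw)
        return cls(**args)

    @classmethod
    def excitatory(cls, **kw) -> "TheoryParams":
        """Excitatory-STDP strand: effective amplitudes 0.02 / 0.021
        (depression slightly dominating)."""
        args = dict(A_plus=0.02, A_minus=0.021)
        args.update(kw)
        return cls(**args)

    @property
    def delta_v(self) -> float:
        return self.V_thres - self.V_rest

    @property
    def ig_mu(self) -> float:
        """Inverse-Gaussian mean ISI (s)."""
        return 1.0 / self.nu

    @property
    def ig_lambda(self) -> float:
        return self.lam if self.lam is not None else 0.75 / self.nu


@dataclass
class MembraneDistribution:
    """Probability density of the subthreshold membrane potential on a
    grid (mV); integrates to 1 over its support."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        z = np.trapezoid(self.density, self.grid)
        if z <= 0:
            raise ValueError("density must have positive mass")
        self.density = self.density / z

    def cdf_above(self, v: float) -> float:
        """Mass at potentials >= v."""
        g, d = self.grid, self.density
        if v <= g[0]:
            return 1.0
        if v >= g[-1]:
            return 0.0
        i = np.searchsorted(g, v)
        # partial trapezoid on the straddling interval
        frac = np.interp(v, g, d)
        part = 0.5 * (frac + d[i]) * (g[i] - v)
        rest = np.trapezoid(d[i:], g[i:])
        return float(part + rest)


# ---------------------------------------------------------------------------
# inhibitory strand (delay, stationary weight, compensated rate)
# ---------------------------------------------------------------------------

def inhibitory_delay(w: float, params: TheoryParams) -> float:
    """Average postsynaptic delay (s) caused by one inhibitory spike of
    strength w (mV): w / (nu0 (V_thres - V_rest))."""
    if w < 0:
        raise ValueError("weight must be non-negative")
    if params.nu_0 <= 0:
        raise ValueError("nu_0 must be positive")
    return w / (params.nu_0 * params.delta_v)


def stationary_inhibitory_weight(nu_0: float, params: TheoryParams) -> float:
    """Stationary inhibitory weight (mV):
    w_stat = nu0 tau (V_thres - V_rest) ln(A+/A-)."""
    if params.A_minus <= 0:
        raise ValueError("A_minus must be positive")
    if params.A_plus < params.A_minus:
        raise ValueError("a non-negative stationary weight needs A_plus >= A_minus")
    tau_s = params.tau / 1000.0
    return nu_0 * tau_s * params.delta_v * math.log(params.A_plus / params.A_minus)


def mean_inhibitory_update(w: float, nu_0: float, params: TheoryParams) -> float:
    """Averaged nearest-neighbour STDP update of the inhibitory synapse:

    <dw> = nu0 tau (1 - e^{-1/(nu0 tau)}) (A+ e^{-w/(nu0 tau dV)} - A-).

    Zero exactly at the stationary weight.
    """
    tau_s = params.tau / 1000.0
    x = nu_0 * tau_s
    return x * (1.0 - math.exp(-1.0 / x)) * (
        params.A_plus * math.exp(-w / (x * params.delta_v)) - params.A_minus)


def rate_with_inhibition(nu_0: float, params: TheoryParams) -> float:
    """Postsynaptic rate once the plastic inhibitory synapse has reached
    its stationary weight: nu0 / (1 + tau nu_inh ln(A+/A-)).

    Strictly increasing in nu0 with slope < 1: extra drive is compensated
    only partially.
    """
    if params.nu_inh < 0:
        raise ValueError("nu_inh must be non-negative")
    tau_s = params.tau / 1000.0
    return nu_0 / (1.0 + tau_s * params.nu_inh
                   * math.log(params.A_plus / params.A_minus))


# ---------------------------------------------------------------------------
# excitatory strand (triplet pair contribution, shift, Eq-6 estimate)
# ---------------------------------------------------------------------------

def pair_contribution(T: float, params: TheoryParams) -> float:
    """Net STDP contribution of one presynaptic spike uniformly placed in
    a postsynaptic ISI of length T (s), ignoring its dynamical effect:

    integral_0^T [A+ e^{-(T-t)/tau} - A- e^{-t/tau}] dt
      = tau (A+ - A-) (1 - e^{-T/tau})   for tau_+ = tau_- = tau.

    Negative for all T when depression dominates (A- > A+); tends to
    A+ tau_+ - A- tau_- (the kernel integrals) as T grows.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    tau_s = params.tau / 1000.0
    em = -math.expm1(-T / tau_s)
    return tau_s * (params.A_plus - params.A_minus) * em


def _shifted_pair_contribution(T: float, s: float, params: TheoryParams) -> float:
    """Pair contribution with the next postsynaptic spike shifted back by
    s (s): the presynaptic spike at offset t in (s, T-s] sees the next
    postsynaptic spike at lag T - t - s, while offsets in [0, s] (spikes
    just after the previous postsynaptic one) are unaffected.  The window
    (T-s, T] where the presynaptic spike itself can trigger firing is
    excluded (handled by the direct-trigger term).
    """
    tau_s = params.tau / 1000.0
    ap, am = params.A_plus, params.A_minus
    if s <= 0:
        return pair_contribution(T, params)
    if T <= 2 * s:
        # degenerate short intervals: only the unshifted head remains
        head = min(s, T)
        return (ap * tau_s * (math.exp(-(T - head) / tau_s)
                              - math.exp(-T / tau_s))
                - am * tau_s * (-math.expm1(-head / tau_s)))
    # shifted middle: t in (s, T-s], potentiation lag T - t - s
    mid_pot = ap * tau_s * (math.exp(-0.0 / tau_s)
                            - math.exp(-(T - 2 * s) / tau_s))
    mid_dep = am * tau_s * (math.exp(-s / tau_s) - math.exp(-(T - s) / tau_s))
    # unshifted head: t in [0, s]
    head_pot = ap * tau_s * (math.exp(-(T - s) / tau_s) - math.exp(-T / tau_s))
    head_dep = am * tau_s * (-math.expm1(-s / tau_s))
    return (mid_pot - mid_dep) + (head_pot - head_dep)


def postsynaptic_shift(w: float, params: TheoryParams) -> float:
    """Average backward time-shift (s) of the next postsynaptic spike
    caused by one presynaptic spike of strength w (mV):
    dr(w) / (r (r + dr(w))) with dr(w) = delta_r_slope * w."""
    r = params.nu
    if r <= 0:
        raise ValueError("postsynaptic rate must be positive")
    dr = params.delta_r_slope * w
    if r + dr <= 0:
        raise ValueError("rate change would make the total rate non-positive")
    return dr / (r * (r + dr))


def fire_probability(w: float, dist: MembraneDistribution,
                     params: TheoryParams) -> float:
    """Probability that a presynaptic spike of strength w (mV) directly
    triggers a postsynaptic spike: membrane-potential mass within w of
    threshold."""
    if w < 0:
        raise ValueError("weight must be non-negative")
    if w == 0:
        return 0.0
    return dist.cdf_above(params.V_thres - w)


def diffusion_membrane_density(mu_in: float, sigma_in: float,
                               V_rest: float = -60.0, V_thres: float = -50.0,
                               V_reset: float = -60.0, tau_m: float = 20.0,
                               n_grid: int = 400) -> MembraneDistribution:
    """Stationary membrane-potential density of a Poisson-driven LIF cell
    in the diffusion approximation.

    ``mu_in`` is the stationary mean input potential (mV above V_rest) and
    ``sigma_in`` the diffusion noise scale with sigma^2 = J^2 R tau_m for
    delta inputs of size J (mV) at total rate R (kHz equivalent, i.e.
    per-ms); the free-membrane variance is sigma^2 / 2.  The standard
    balanced-network form: with y = (V - V_rest - mu_in)/sigma,
    P(V) propto exp(-y^2) * integral_{max(y, y_reset)}^{y_thres} e^{u^2} du,
    normalized on [V_low, V_thres].
    """
    sigma = max(sigma_in, 1e-9)
    y_th = (V_thres - V_rest - mu_in) / sigma
    y_re = (V_reset - V_rest - mu_in) / sigma
    v_lo = min(V_reset, V_rest + mu_in - 6.0 * sigma)
    grid = np.linspace(v_lo, V_thres, n_grid)
    y = (grid - V_rest - mu_in) / sigma

    from scipy.special import erfi
    # integral of e^{u^2} du = sqrt(pi)/2 * erfi(u)
    upper = erfi(y_th)
    dens = np.empty_like(y)
    for i, yi in enumerate(y):
        lo = max(yi, y_re)
        dens[i] = math.exp(-yi * yi) * max(0.0, upper - erfi(lo))
    return MembraneDistribution(grid, dens)


def membrane_distribution(source: str, *, trace: np.ndarray | None = None,
                          refractory: np.ndarray | None = None,
                          mu_in: float | None = None,
                          sigma_in: float | None = None,
                          V_rest: float = -60.0, V_thres: float = -50.0,
                          V_reset: float = -60.0, tau_m: float = 20.0,
                          n_grid: int = 200) -> MembraneDistribution:
    """Membrane-potential distribution, empirical or diffusion-theoretic.

    ``empirical``: normalized histogram of subthreshold voltage samples
    (samples flagged refractory are excluded).  ``diffusion``: stationary
    density of the Poisson-driven LIF cell given the input mean and SD.
    """
    if source == "empirical":
        if trace is None or len(trace) == 0:
            raise ValueError("empirical mode needs a non-empty voltage trace")
        v = np.asarray(trace, dtype=float)
        if refractory is not None:
            v = v[~np.asarray(refractory, dtype=bool)]
        if v.size == 0:
            raise ValueError("no subthreshold samples left")
        if v.max() - v.min() < 1e-12:
            # degenerate: all mass at one potential
            g = np.array([v[0] - 1e-6, v[0], v[0] + 1e-6])
            return MembraneDistribution(g, np.array([0.0, 1.0, 0.0]))
        counts, edges = np.histogram(v, bins=n_grid, density=True)
        centers = (edges[:-1] + edges[1:]) / 2.0
        return MembraneDistribution(centers, counts)
    if source == "diffusion":
        if mu_in is None or sigma_in is None:
            raise ValueError("diffusion mode needs mu_in and sigma_in")
        return diffusion_membrane_density(mu_in, sigma_in, V_rest, V_thres,
                                          V_reset, tau_m)
    raise ValueError("source must be 'empirical' or 'diffusion'")


def expected_weight_change(w: float, params: TheoryParams,
                           dist: MembraneDistribution,
                           rtol: float = 1e-6) -> float:
    """Mean STDP update per presynaptic spike at frozen weight w (mV).

    nu * E_T[shifted pair contribution] + P_fire(w) * A+ e^{-tau_syn/tau},
    with T ~ InverseGaussian(mu = 1/nu, lambda) for the postsynaptic ISI.
    The nu prefactor converts the ISI-density integral into the
    per-presynaptic-spike expectation (a uniform presynaptic spike lands
    in an ISI with length-biased probability).  Quadrature runs to the
    1 - 1e-6 quantile of the ISI distribution at relative tolerance
    ``rtol``.
    """
    if w < 0:
        raise ValueError("weight must be non-negative")
    mu, lam = params.ig_mu, params.ig_lambda
    ig = stats.invgauss(mu / lam, scale=lam)
    s = postsynaptic_shift(w, params) if params.delta_r_slope else 0.0
    t_hi = float(ig.ppf(1.0 - 1e-6))

    def integrand(T):
        return ig.pdf(T) * _shifted_pair_contribution(T, s, params)

    val, _ = integrate.quad(integrand, 0.0, t_hi, epsrel=rtol, limit=200)
    trigger = fire_probability(w, dist, params) * params.A_plus * math.exp(
        -params.tau_syn / params.tau)
    return params.nu * val + trigger


def fit_rate_slope(w_grid, rates) -> tuple[float, float, float]:
    """Linear fit of the postsynaptic rate change against synaptic weight.

    Returns (slope in Hz/mV, intercept rate at w=0, RMS residual); the
    slope is the ``delta_r_slope`` the shift formula consumes.
    """
    w = np.asarray(w_grid, dtype=float)
    r = np.asarray(rates, dtype=float)
    if w.size < 2:
        raise ValueError("need at least two grid points")
    coef = np.polyfit(w, r, 1)
    resid = r - np.polyval(coef, w)
    return float(coef[0]), float(coef[1]), float(np.sqrt((resid ** 2).mean()))
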