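"""Network parameters and graph construction.

A network holds ``n_e`` excitatory and ``n_i`` inhibitory leaky
integrate-and-fire cells wired by four directed connection classes
(E-E, E-I, I-E, I-I).  Excitatory cells carry ids ``0..n_e-1`` and
inhibitory cells ``n_e..n_e+n_i-1``.  Connections are mono-synaptic
(at most one directed edge per ordered pair) and never self-connecting.

Three constructors are provided:

* :func:`build_random_topology` -- Erdős–Rényi wiring with a single
  connection probability ``p`` for all four classes (the base model:
  4000 E + 1000 I, p = 0.02).
* :func:`build_homogeneous_topology` -- every cell receives exactly the
  same number of excitatory and inhibitory inputs (used to show that
  driver cells need in-degree heterogeneity to emerge).
* :func:`build_torus_topology` -- topographic wiring on the unit torus
  with Gaussian distance-dependent connection profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "ConnectivityProfile",
    "Topology",
    "CLASSES",
    "build_random_topology",
    "build_homogeneous_topology",
    "torus_distance",
    "torus_connection_probability",
    "build_torus_topology",
    "init_weights",
    "prune_inhibitory_inputs",
    "expected_subgroup_connections",
]

#: connection-class keys: presynaptic class first ("ie" = I -> E).
CLASSES = ("ee", "ei", "ie", "ii")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire single-cell parameters.

    Defaults are the base model's: membrane time constant 20 ms, leak
    reversal -60 mV, spike threshold -50 mV, reset -60 mV, absolute
    refractory period 2 ms.
    """

    tau_m: float = 20.0      # membrane time constant (ms)
    E_L: float = -60.0       # leak reversal (mV)
    V_thres: float = -50.0   # spike threshold (mV)
    V_reset: float = -60.0   # post-spike reset (mV)
    tau_ref: float = 2.0     # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be non-negative")
        if not (self.V_reset <= self.E_L < self.V_thres):
            raise ValueError("require V_reset <= E_L < V_thres")


@dataclass(frozen=True)
class SynapseParams:
    """Current-based exponential synapse parameters.

    ``c_e_norm``/``c_i_norm`` are the current normalisation factors (mV);
    the inhibitory one is stored as the printed signed value (-9 mV) and
    enters the membrane equation hyperpolarising.  Unit-weight PSPs
    calibrate to +0.16 mV (EPSP) and -2.25 mV (IPSP).
    """

    tau_e: float = 5.0       # excitatory synaptic time constant (ms)
    tau_i: float = 10.0      # inhibitory synaptic time constant (ms)
    c_e_norm: float = 1.0    # excitatory current factor (mV)
    c_i_norm: float = -9.0   # inhibitory current factor (mV, signed)
    w_e_max: float = 20.0    # maximal excitatory weight (dimensionless)
    w_i_max: float = 5.0     # maximal inhibitory weight (dimensionless)

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.w_e_max <= 0 or self.w_i_max <= 0:
            raise ValueError("maximal weights must be positive")
        if self.c_e_norm <= 0:
            raise ValueError("c_e_norm must be positive")
        if self.c_i_norm >= 0:
            raise ValueError("c_i_norm is a signed factor and must be negative")

    def w_max(self, cls: str) -> float:
        """Weight ceiling for a connection class ('ee','ei' -> w_e_max)."""
        return self.w_e_max if cls in ("ee", "ei") else self.w_i_max


@dataclass(frozen=True)
class ConnectivityProfile:
    """Gaussian distance-dependent connection profile on the torus.

    Connection probability at distance d is ``epsilon * exp(-d^2/(2 sigma^2))``.
    """

    epsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# profiles of the topographic variant (E: wide and sparse, I: local and dense)
E_TORUS_PROFILE = ConnectivityProfile(epsilon=0.2, sigma=0.1)
I_TORUS_PROFILE = ConnectivityProfile(epsilon=0.8, sigma=0.05)


@dataclass
class Topology:
    """Directed weighted network over the four connection classes.

    Weights live in CSR matrices keyed by class, shaped
    (n of presynaptic class, n of postsynaptic class), rows = presynaptic
    cell index *within its class*.  ``positions`` optionally stores unit
    torus coordinates for all ``n_e + n_i`` cells (excitatory first).
    """

    n_e: int
    n_i: int
    w: dict[str, sp.csr_matrix] = field(default_factory=dict)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            "ee": (self.n_e, self.n_e),
            "ei": (self.n_e, self.n_i),
            "ie": (self.n_i, self.n_e),
            "ii": (self.n_i, self.n_i),
        }
        for cls in CLASSES:
            m = self.w.get(cls)
            if m is None:
                self.w[cls] = sp.csr_matrix(shapes[cls])
            else:
                m = sp.csr_matrix(m)
                if m.shape != shapes[cls]:
                    raise ValueError(f"class {cls}: expected shape {shapes[cls]}, got {m.shape}")
                m.sum_duplicates()
                if cls in ("ee", "ii") and m.diagonal().any():
                    raise ValueError(f"class {cls}: self-edges are not allowed")
                self.w[cls] = m

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    def n_edges(self, cls: str) -> int:
        return int(self.w[cls].nnz)

    def copy(self) -> "Topology":
        return Topology(
            self.n_e,
            self.n_i,
            {cls: self.w[cls].copy() for cls in CLASSES},
            None if self.positions is None else self.positions.copy(),
        )

    def in_degrees(self, cls: str) -> np.ndarray:
        """Number of incoming edges of the given class per postsynaptic cell.

        Edges are structural: a synapse whose weight plasticity has driven
        to exactly zero still counts.
        """
        return np.diff(self.w[cls].tocsc().indptr)

    def out_degrees(self, cls: str) -> np.ndarray:
        return np.diff(self.w[cls].tocsr().indptr)


# ---------------------------------------------------------------------------
# random (Erdős–Rényi) wiring
# ---------------------------------------------------------------------------

def _sample_pairs(rng: np.random.Generator, n_pre: int, n_post: int,
                  p: float, exclude_diagonal: bool) -> tuple[np.ndarray, np.ndarray]:
    """Sample each ordered (pre, post) pair independently with probability p.

    The number of edges is drawn Binomial(#pairs, p) and that many distinct
    pairs are sampled uniformly (over-sample with replacement, deduplicate,
    subsample) -- equivalent in distribution to per-pair Bernoulli trials
    but O(edges) instead of O(pairs).
    """
    n_pairs = n_pre * n_post - (min(n_pre, n_post) if exclude_diagonal else 0)
    if n_pairs <= 0 or p == 0.0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = int(rng.binomial(n_pairs, p))
    if m == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if m > 0.2 * n_pairs:
        # dense regime: explicit Bernoulli mask is cheap enough
        mask = rng.random((n_pre, n_post)) < p
        if exclude_diagonal:
            np.fill_diagonal(mask, False)
        pre, post = np.nonzero(mask)
        return pre.astype(np.int64), post.astype(np.int64)
    chosen = np.empty(0, dtype=np.int64)
    while chosen.size < m:
        extra = int(1.1 * (m - chosen.size)) + 16
        cand = rng.integers(0, n_pairs, size=extra)
        chosen = np.unique(np.concatenate([chosen, cand]))
    if chosen.size > m:
        chosen = rng.choice(chosen, size=m, replace=False)
    if exclude_diagonal:
        # index space excludes the diagonal: per row there are n_post-1 slots
        pre = chosen // (n_post - 1)
        j = chosen % (n_post - 1)
        post = j + (j >= pre)
    else:
        pre = chosen // n_post
        post = chosen % n_post
    return pre.astype(np.int64), post.astype(np.int64)


def _csr_from_pairs(pre: np.ndarray, post: np.ndarray, shape: tuple[int, int],
                    weight: float = 1.0) -> sp.csr_matrix:
    data = np.full(pre.size, weight, dtype=np.float64)
    return sp.csr_matrix((data, (pre, post)), shape=shape)


def build_random_topology(n_e: int, n_i: int, p: float, seed: int) -> Topology:
    """Erdős–Rényi network: every ordered non-self pair in every class is
    connected independently with probability ``p``; initial weights 1."""
    if n_e < 0 or n_i < 0:
        raise ValueError("population sizes must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    w = {}
    for cls, (npre, npost, diag) in {
        "ee": (n_e, n_e, True),
        "ei": (n_e, n_i, False),
        "ie": (n_i, n_e, False),
        "ii": (n_i, n_i, True),
    }.items():
        pre, post = _sample_pairs(rng, npre, npost, p, diag)
        w[cls] = _csr_from_pairs(pre, post, (npre, npost))
    return Topology(n_e, n_i, w)


def build_homogeneous_topology(n_e: int, n_i: int, k_e_in: int, k_i_in: int,
                               seed: int) -> Topology:
    """Network in which every cell has exactly ``k_e_in`` excitatory and
    ``k_i_in`` inhibitory presynaptic partners (out-degrees remain random).

    Partners are drawn without replacement, excluding the cell itself.
    """
    if n_e < 0 or n_i < 0:
        raise ValueError("population sizes must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(pool: int, k: int, n_targets: int, self_idx_of=None):
        """For each target, sample k distinct presynaptic ids from `pool`."""
        if k < 0:
            raise ValueError("in-degree must be non-negative")
        pre_rows, post_cols = [], []
        for t in range(n_targets):
            forbidden = self_idx_of(t) if self_idx_of is not None else None
            avail = pool - (1 if forbidden is not None else 0)
            if k > avail:
                raise ValueError(
                    f"requested in-degree {k} exceeds available presynaptic pool {avail}")
            choice = rng.choice(pool - (1 if forbidden is not None else 0),
                                size=k, replace=False)
            if forbidden is not None:
                choice = choice + (choice >= forbidden)
            pre_rows.append(choice)
            post_cols.append(np.full(k, t, dtype=np.int64))
        if not pre_rows:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        return np.concatenate(pre_rows), np.concatenate(post_cols)

    w = {}
    pre, post = draw(n_e, k_e_in, n_e, self_idx_of=lambda t: t)
    w["ee"] = _csr_from_pairs(pre, post, (n_e, n_e))
    pre, post = draw(n_e, k_e_in, n_i)
    w["ei"] = _csr_from_pairs(pre, post, (n_e, n_i))
    pre, post = draw(n_i, k_i_in, n_e)
    w["ie"] = _csr_from_pairs(pre, post, (n_i, n_e))
    pre, post = draw(n_i, k_i_in, n_i, self_idx_of=lambda t: t)
    w["ii"] = _csr_from_pairs(pre, post, (n_i, n_i))
    return Topology(n_e, n_i, w)


# ---------------------------------------------------------------------------
# topographic wiring on the unit torus
# ---------------------------------------------------------------------------

def torus_distance(a, b) -> float | np.ndarray:
    """Euclidean distance on the unit torus [0,1)^2 (per-axis wraparound)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.abs(a - b)
    d = np.minimum(d, 1.0 - d)
    out = np.sqrt((d * d).sum(axis=-1))
    return float(out) if out.ndim == 0 else out


def torus_connection_probability(d, profile: ConnectivityProfile):
    """Gaussian profile epsilon * exp(-d^2 / (2 sigma^2))."""
    d = np.asarray(d, dtype=float)
    out = profile.epsilon * np.exp(-(d * d) / (2.0 * profile.sigma ** 2))
    return float(out) if out.ndim == 0 else out


def _grid_positions(n: int) -> np.ndarray:
    side = int(round(math.sqrt(n)))
    if side * side != n:
        raise ValueError("grid placement requires a perfect-square count")
    off = 1.0 / (2 * side)
    u, v = np.meshgrid(np.arange(side) / side + off, np.arange(side) / side + off)
    return np.column_stack([u.ravel(), v.ravel()])


def build_torus_topology(n_e: int, n_i: int,
                         e_profile: ConnectivityProfile = E_TORUS_PROFILE,
                         i_profile: ConnectivityProfile = I_TORUS_PROFILE,
                         i_placement: str = "uniform",
                         seed: int = 0) -> Topology:
    """Topographic network on the unit torus.

    Excitatory positions are uniform; inhibitory positions uniform or on a
    regular sqrt(n_i) x sqrt(n_i) lattice.  Each ordered pair (a, b), a != b,
    is connected with probability given by the *presynaptic* cell's class
    profile evaluated at the torus distance.
    """
    if i_placement not in ("uniform", "grid"):
        raise ValueError("i_placement must be 'uniform' or 'grid'")
    rng = np.random.default_rng(seed)
    pos_e = rng.random((n_e, 2))
    pos_i = _grid_positions(n_i) if i_placement == "grid" else rng.random((n_i, 2))
    pos = np.vstack([pos_e, pos_i])

    def wire(pre_pos, post_pos, profile, exclude_diag):
        npre, npost = len(pre_pos), len(post_pos)
        rows_pre, rows_post = [], []
        chunk = max(1, int(4e6) // max(npost, 1))
        for lo in range(0, npre, chunk):
            hi = min(npre, lo + chunk)
            du = np.abs(pre_pos[lo:hi, None, 0] - post_pos[None, :, 0])
            dv = np.abs(pre_pos[lo:hi, None, 1] - post_pos[None, :, 1])
            du = np.minimum(du, 1.0 - du)
            dv = np.minimum(dv, 1.0 - dv)
            pconn = profile.epsilon * np.exp(-(du * du + dv * dv)
                                             / (2.0 * profile.sigma ** 2))
            mask = rng.random(pconn.shape) < pconn
            if exclude_diag:
                for r in range(lo, hi):
                    mask[r - lo, r] = False
            a, b = np.nonzero(mask)
            rows_pre.append(a + lo)
            rows_post.append(b)
        pre = np.concatenate(rows_pre) if rows_pre else np.empty(0, np.int64)
        post = np.concatenate(rows_post) if rows_post else np.empty(0, np.int64)
        return _csr_from_pairs(pre, post, (npre, npost))

    w = {
        "ee": wire(pos_e, pos_e, e_profile, True),
        "ei": wire(pos_e, pos_i, e_profile, False),
        "ie": wire(pos_i, pos_e, i_profile, False),
        "ii": wire(pos_i, pos_i, i_profile, True),
    }
    return Topology(n_e, n_i, w, positions=pos)


# ---------------------------------------------------------------------------
# weight initialisation and surgery
# ---------------------------------------------------------------------------

def init_weights(topology: Topology, scheme: str = "constant",
                 params: dict | None = None, seed: int = 0,
                 synapse: SynapseParams = SynapseParams()) -> Topology:
    """Assign initial weights on the existing edges of every class.

    schemes: ``constant`` (value, default 1), ``gaussian`` (mean, sd),
    ``uniform`` (low, high).  Results are clipped to [0, class maximum].
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    out = topology.copy()
    for cls in CLASSES:
        m = out.w[cls]
        n = m.nnz
        if scheme == "constant":
            vals = np.full(n, float(params.get("value", 1.0)))
        elif scheme == "gaussian":
            sd = float(params.get("sd", 0.0))
            if sd < 0:
                raise ValueError("gaussian sd must be non-negative")
            vals = rng.normal(float(params.get("mean", 1.0)), sd, size=n)
        elif scheme == "uniform":
            vals = rng.uniform(float(params.get("low", 0.0)),
                               float(params.get("high", 2.0)), size=n)
        else:
            raise ValueError(f"unknown weight scheme {scheme!r}")
        m.data[:] = np.clip(vals, 0.0, synapse.w_max(cls))
    return out


def prune_inhibitory_inputs(topology: Topology, target_ids, fraction: float,
                            seed: int = 0) -> Topology:
    """Remove round(fraction * k) randomly chosen incoming I-E edges from each
    target cell (ids are excitatory).  Other classes are untouched.

    Rounding is half-away-from-zero so fraction 0.1 on 15 inputs removes 2.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    target_ids = np.asarray(list(target_ids), dtype=np.int64)
    if target_ids.size and (target_ids.min() < 0 or target_ids.max() >= topology.n_e):
        raise ValueError("target ids must be excitatory cell ids")
    rng = np.random.default_rng(seed)
    out = topology.copy()
    ie = out.w["ie"].tocsc()
    keep = np.ones(ie.nnz, dtype=bool)
    for t in target_ids:
        lo, hi = ie.indptr[t], ie.indptr[t + 1]
        k = hi - lo
        n_remove = int(math.floor(fraction * k + 0.5))
        if n_remove:
            drop = rng.choice(k, size=n_remove, replace=False)
            keep[lo + drop] = False
    data = ie.data[keep]
    rows = ie.indices[keep]
    cols = np.repeat(np.arange(topology.n_e), np.diff(ie.indptr))[keep]
    out.w["ie"] = sp.csr_matrix((data, (rows, cols)), shape=ie.shape)
    return out


def expected_subgroup_connections(n: int, p: float) -> float:
    """Expected number of directed edges inside an n-cell subgroup of an
    Erdős–Rényi network with connection probability p: n(n-1)p."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return n * (n - 1) * p
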