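"""Spike-train and weight statistics.

Everything the downstream experiments measure lives here: firing rates
and ISI variability, driver-cell detection (extreme mean outgoing E-E
weight, by percentile or by standard-deviation threshold), weight-shuffle
surrogates, subgroup connectivity counts, synchrony-triggered averages,
PSTHs, and the long-tail distribution fits (continuous power-law MLE with
KS-based lower-bound selection and an upper trim, plus log-normal MLE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .dynamics import SpikeRecord
from .topology import Topology

__all__ = [
    "DriverReport",
    "PowerLawFit",
    "firing_rates",
    "cv_isi",
    "mean_outgoing_weight",
    "mean_outgoing_weights",
    "detect_drivers_percentile",
    "detect_drivers_sd",
    "shuffle_weight_surrogate",
    "count_subgroup_connections",
    "synchrony_triggered_average",
    "fit_powerlaw_mle",
    "fit_lognormal",
    "psth",
]


@dataclass
class DriverReport:
    """Result of driver-cell detection.

    Cells without outgoing E-E edges are excluded from the ranking.
    Every reported driver's mean outgoing weight is >= ``threshold``.
    """

    method: str                       # "percentile" or "sd"
    threshold: float                  # weight threshold actually applied
    driver_ids: np.ndarray            # excitatory cell ids, ascending
    mean_outgoing: np.ndarray         # per-cell mean outgoing E-E weight (NaN if unranked)
    parameter: float = 0.0            # fraction or k_sd used


@dataclass
class PowerLawFit:
    """Continuous power-law fit p(x) ~ x^alpha on [x_min, upper trim bound].

    ``alpha`` follows the density-exponent sign convention (negative).
    """

    alpha: float
    x_min: float
    upper_trim_fraction: float
    upper_bound: float
    ks_distance: float
    n_tail: int


# ---------------------------------------------------------------------------
# rates and ISI statistics
# ---------------------------------------------------------------------------

def firing_rates(spikes: SpikeRecord, window: tuple[float, float]) -> np.ndarray:
    """Per-neuron firing rate (Hz) over the half-open window [t0, t1) in ms."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window length must be positive")
    m = (spikes.times >= t0) & (spikes.times < t1)
    counts = np.bincount(spikes.ids[m], minlength=spikes.n_total)
    return counts / ((t1 - t0) / 1000.0)


def cv_isi(spike_times) -> float:
    """Coefficient of variation of inter-spike intervals: SD(ISI)/mean(ISI).

    Needs at least 3 spikes (2 intervals); returns NaN otherwise.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 3:
        return float("nan")
    isi = np.diff(np.sort(t))
    m = isi.mean()
    return float(isi.std() / m) if m > 0 else float("nan")


# ---------------------------------------------------------------------------
# driver detection
# ---------------------------------------------------------------------------

def mean_outgoing_weights(topology: Topology) -> np.ndarray:
    """Per-excitatory-cell mean outgoing E-E weight; NaN for cells with
    zero E-E out-degree (excluded from any ranking)."""
    ee = topology.w["ee"].tocsr()
    # structural out-degree: synapses silenced by plasticity still count
    deg = np.diff(ee.indptr).astype(float)
    sums = np.asarray(ee.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / deg
    out[deg == 0] = np.nan
    return out


def mean_outgoing_weight(topology: Topology, cell: int) -> float:
    """Mean outgoing E-E weight of one excitatory cell (NaN if none)."""
    if not 0 <= cell < topology.n_e:
        raise ValueError("cell must be an excitatory id")
    return float(mean_outgoing_weights(topology)[cell])


def _ranked(values: np.ndarray):
    ranked = np.flatnonzero(~np.isnan(values))
    return ranked


def detect_drivers_percentile(topology: Topology, fraction: float = 0.005
                              ) -> DriverReport:
    """Driver cells = the top ``fraction`` of ranked excitatory cells by
    mean outgoing E-E weight (round(fraction * n_ranked) cells; ties broken
    towards lower ids).  The base network's 0.5% of 4000 cells gives 20."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    means = mean_outgoing_weights(topology)
    ranked = _ranked(means)
    k = int(round(fraction * ranked.size))
    if k == 0:
        return DriverReport("percentile", float("inf"),
                            np.empty(0, dtype=np.int64), means, fraction)
    # sort by (-weight, id): deterministic tie-break towards lower id
    order = np.lexsort((ranked, -means[ranked]))
    chosen = ranked[order[:k]]
    threshold = float(means[chosen].min())
    return DriverReport("percentile", threshold, np.sort(chosen), means,
                        fraction)


def detect_drivers_sd(topology: Topology, k_sd: float = 3.0) -> DriverReport:
    """Driver cells = ranked excitatory cells whose mean outgoing E-E
    weight exceeds mean + k_sd * SD of the per-cell means."""
    means = mean_outgoing_weights(topology)
    ranked = _ranked(means)
    if ranked.size < 2:
        raise ValueError("need at least 2 ranked cells")
    mu = means[ranked].mean()
    sd = means[ranked].std()
    threshold = mu + k_sd * sd
    if sd == 0:
        return DriverReport("sd", float(threshold),
                            np.empty(0, dtype=np.int64), means, k_sd)
    chosen = ranked[means[ranked] > threshold]
    return DriverReport("sd", float(threshold), np.sort(chosen), means, k_sd)


def shuffle_weight_surrogate(topology: Topology, n_shuffles: int = 100,
                             seed: int = 0):
    """Quantile curves of per-cell mean outgoing E-E weight after shuffling
    the weights over the existing E-E edges.

    Shuffling keeps the edge set and weight multiset fixed, destroying
    only the cell-wise clustering of strong weights.  Returns
    (sorted_original, surrogate_mean, surrogate_sd), each of length
    n_ranked (ascending quantiles).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    original = mean_outgoing_weights(topology)
    ranked = _ranked(original)
    ee = topology.w["ee"].tocsr().copy()
    deg = np.diff(ee.indptr).astype(float)
    curves = np.empty((n_shuffles, ranked.size))
    data = ee.data
    for s in range(n_shuffles):
        perm = rng.permutation(data.size)
        shuf = data[perm]
        sums = np.add.reduceat(shuf, ee.indptr[:-1][deg > 0])
        means = np.full(topology.n_e, np.nan)
        means[deg > 0] = sums / deg[deg > 0]
        curves[s] = np.sort(means[ranked])
    return (np.sort(original[ranked]), curves.mean(axis=0), curves.std(axis=0))


def count_subgroup_connections(topology: Topology, ids) -> int:
    """Number of directed E-E edges (a, b) with both endpoints in ``ids``."""
    ids = np.asarray(list(ids), dtype=np.int64)
    if np.unique(ids).size != ids.size:
        raise ValueError("ids must be distinct")
    m = topology.w["ee"].tocsr()
    # count structural edges (indicator matrix survives explicit zeros)
    import scipy.sparse as sp
    struct = sp.csr_matrix((np.ones(m.nnz), m.indices.copy(),
                            m.indptr.copy()), shape=m.shape)
    return int(struct[np.ix_(ids, ids)].sum())


# ---------------------------------------------------------------------------
# event-triggered population statistics
# ---------------------------------------------------------------------------

def _population_rate(spikes: SpikeRecord, bin_ms: float, pop: str = "e"):
    """(bin edges, rate trace in Hz) of the excitatory population."""
    n = spikes.n_e if pop == "e" else spikes.n_total
    t_max = spikes.duration
    n_bins = max(1, int(np.ceil(t_max / bin_ms)))
    sel = spikes.ids < spikes.n_e if pop == "e" else slice(None)
    counts, edges = np.histogram(spikes.times[sel],
                                 bins=n_bins, range=(0.0, n_bins * bin_ms))
    return edges, counts / (n * bin_ms / 1000.0)


def synchrony_triggered_average(spikes: SpikeRecord, group_ids, k: int,
                                bin_ms: float = 1.0, halfwidth: float = 100.0):
    """Average excitatory population rate around moments when >= k group
    members spike inside one ``bin_ms`` bin.

    Events closer than one halfwidth to a previous event are collapsed to
    the first; events whose window leaves the record are skipped.  Returns
    (lag_ms, mean rate trace in Hz, n_events); empty arrays if no events.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    group_ids = np.asarray(list(group_ids), dtype=np.int64)
    edges, rate = _population_rate(spikes, bin_ms)
    in_group = np.isin(spikes.ids, group_ids)
    g_counts, _ = np.histogram(spikes.times[in_group], bins=edges)
    # distinct members, not spike count: a cell cannot fire twice in 1 ms
    # bins when bin <= refractory period, so counts are a safe proxy there;
    # recompute exactly otherwise
    if bin_ms > 2.0:
        hits = np.zeros(len(edges) - 1, dtype=np.int64)
        bidx = np.minimum((spikes.times[in_group] / bin_ms).astype(int),
                          len(hits) - 1)
        for b in np.unique(bidx):
            hits[b] = np.unique(spikes.ids[in_group][bidx == b]).size
        g_counts = hits
    event_bins = np.flatnonzero(g_counts >= k)
    half_bins = int(round(halfwidth / bin_ms))
    chosen = []
    last = -np.inf
    for b in event_bins:
        if b - last < half_bins:
            continue
        if b - half_bins < 0 or b + half_bins + 1 > rate.size:
            continue
        chosen.append(b)
        last = b
    if not chosen:
        return np.empty(0), np.empty(0), 0
    traces = np.stack([rate[b - half_bins:b + half_bins + 1] for b in chosen])
    lags = (np.arange(-half_bins, half_bins + 1)) * bin_ms
    return lags, traces.mean(axis=0), len(chosen)


def psth(spikes: SpikeRecord, bin_ms: float, alignment_times,
         window: tuple[float, float] = (-100.0, 100.0), pop: str = "e"):
    """Population rate (Hz) binned around each alignment time and averaged.

    Returns (bin centers relative to alignment, mean rate).  Bins that
    fall outside the record contribute zeros (the record is taken as the
    complete spike list of its window).
    """
    if bin_ms <= 0:
        raise ValueError("bin must be positive")
    align = np.atleast_1d(np.asarray(alignment_times, dtype=float))
    lo, hi = window
    edges = np.arange(lo, hi + bin_ms * 0.5, bin_ms)
    n = spikes.n_e if pop == "e" else spikes.n_total
    sel = spikes.ids < spikes.n_e if pop == "e" else slice(None)
    t = spikes.times[sel]
    acc = np.zeros(edges.size - 1)
    for a in align:
        counts, _ = np.histogram(t - a, bins=edges)
        acc += counts
    rate = acc / (align.size * n * bin_ms / 1000.0)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, rate


# ---------------------------------------------------------------------------
# long-tail distribution fits
# ---------------------------------------------------------------------------

def _powerlaw_ks(x: np.ndarray, x_min: float, x_max: float, alpha_mag: float
                 ) -> float:
    """KS distance between the tail sample and the truncated power law
    with density exponent -alpha_mag on [x_min, x_max]."""
    x = np.sort(x)
    if alpha_mag == 1.0:
        cdf = np.log(x / x_min) / np.log(x_max / x_min)
    else:
        a1 = 1.0 - alpha_mag
        cdf = (x ** a1 - x_min ** a1) / (x_max ** a1 - x_min ** a1)
    emp = np.arange(1, x.size + 1) / x.size
    emp0 = np.arange(0, x.size) / x.size
    return float(np.maximum(np.abs(cdf - emp), np.abs(cdf - emp0)).max())


def _truncated_mle(x: np.ndarray, x_min: float, x_max: float) -> float:
    """Magnitude of the density exponent by MLE for the power law
    truncated to [x_min, x_max] (numerical likelihood maximization)."""
    from scipy.optimize import minimize_scalar

    mean_log = np.log(x / x_min).mean()
    lr = np.log(x_max / x_min)

    def nll(a):
        # mean negative log-likelihood up to constants; a = |exponent|
        a1 = 1.0 - a
        if abs(a1) < 1e-8:
            log_norm = np.log(lr)
        else:
            # normalizer (x_max^{1-a} - x_min^{1-a})/(1-a), in units of x_min
            z = np.expm1(a1 * lr) / a1
            log_norm = np.log(z)
        return a * mean_log + log_norm

    res = minimize_scalar(nll, bounds=(0.05, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def fit_powerlaw_mle(samples, upper_trim_fraction: float = 0.05,
                     n_xmin_candidates: int = 50,
                     min_tail: int = 50) -> PowerLawFit:
    """Continuous power-law MLE with KS-minimizing lower bound.

    The strongest ``upper_trim_fraction`` of the samples is discarded
    first (the fit targets the middle part of the distribution); the
    lower bound x_min is then chosen over a quantile grid to minimize
    the KS distance between the tail sample and the fitted truncated
    power law, whose exponent is re-estimated by MLE for each candidate.
    Returns the fit with ``alpha`` as the (negative) density exponent.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if not 0.0 <= upper_trim_fraction < 1.0:
        raise ValueError("upper_trim_fraction must lie in [0, 1)")
    if x.size:
        cutoff = np.quantile(x, 1.0 - upper_trim_fraction)
        x = x[x <= cutoff]
    if x.size < min_tail:
        raise ValueError(f"need at least {min_tail} positive samples")
    x_max = float(x.max())
    candidates = np.unique(np.quantile(x, np.linspace(0.0, 0.9,
                                                      n_xmin_candidates)))
    best = None
    for xm in candidates:
        tail = x[x >= xm]
        if tail.size < min_tail or xm <= 0 or xm >= x_max:
            continue
        a = _truncated_mle(tail, xm, x_max)
        ks = _powerlaw_ks(tail, xm, x_max, a)
        if best is None or ks < best[0]:
            best = (ks, xm, a, tail.size)
    if best is None:
        raise ValueError("no viable x_min candidate with enough tail points")
    ks, xm, a, n_tail = best
    return PowerLawFit(alpha=-a, x_min=float(xm),
                       upper_trim_fraction=upper_trim_fraction,
                       upper_bound=x_max, ks_distance=ks, n_tail=int(n_tail))


def fit_lognormal(samples):
    """Log-normal MLE.  Zeros are excluded (their count is reported).

    Returns (mu, sigma, ks_distance, n_zeros_excluded).
    """
    x = np.asarray(samples, dtype=float)
    n_zero = int(np.sum(x <= 0))
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all samples are non-positive")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std())
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        sigma = 0.0
    if sigma == 0:
        return mu, 0.0, 0.0, n_zero
    ks = float(scipy.stats.kstest(logs, "norm", args=(mu, sigma)).statistic)
    return mu, sigma, ks, n_zero
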