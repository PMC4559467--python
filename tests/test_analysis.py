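"""Statistics: rates, ISI CV, driver detection, surrogates, subgroup
connectivity, event-triggered averages, and long-tail fits."""

import numpy as np
import pytest
import scipy.sparse as sp

import drivernet as dn


def topology_with_weights(n_e, weights_matrix):
    topo = dn.Topology(n_e, 0)
    topo.w["ee"] = sp.csr_matrix(weights_matrix)
    return topo


def poisson_record(rate_hz, duration_ms, n_neurons=1, n_e=None, seed=0):
    rng = np.random.default_rng(seed)
    times, ids = [], []
    for i in range(n_neurons):
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        times.append(np.sort(rng.uniform(0, duration_ms, n)))
        ids.append(np.full(n, i))
    t = np.concatenate(times)
    order = np.argsort(t)
    return dn.SpikeRecord(t[order], np.concatenate(ids)[order],
                          n_e or n_neurons, 0, duration_ms)


class TestRatesAndCV:
    def test_rate_count_over_window(self):
        rec = dn.SpikeRecord(np.linspace(0, 1999, 10), np.zeros(10, int),
                             1, 0, 2000.0)
        assert dn.firing_rates(rec, (0, 2000.0))[0] == pytest.approx(5.0)

    def test_silent_neuron_rate_zero(self):
        rec = dn.SpikeRecord([], [], 3, 0, 1000.0)
        assert np.all(dn.firing_rates(rec, (0, 1000.0)) == 0)

    def test_empty_window_rejected(self):
        rec = dn.SpikeRecord([], [], 1, 0, 1000.0)
        with pytest.raises(ValueError):
            dn.firing_rates(rec, (10.0, 10.0))

    def test_poisson_rate_within_counting_error(self):
        rec = poisson_record(20.0, 100_000.0, seed=3)
        r = dn.firing_rates(rec, (0, 100_000.0))[0]
        se = np.sqrt(20.0 / 100.0)
        assert abs(r - 20.0) < 4 * se

    def test_cv_periodic_is_zero(self):
        assert dn.cv_isi(np.arange(0, 1000, 50.0)) == 0.0

    def test_cv_poisson_near_one(self):
        rec = poisson_record(20.0, 500_000.0, seed=4)
        cv = dn.cv_isi(rec.spike_times(0))
        assert cv == pytest.approx(1.0, abs=0.05)

    def test_cv_needs_three_spikes(self):
        assert np.isnan(dn.cv_isi([1.0, 2.0]))


class TestDriverDetection:
    def test_mean_outgoing_weight(self):
        topo = topology_with_weights(3, [[0, 2.0, 4.0], [0, 0, 0], [0, 0, 0]])
        assert dn.mean_outgoing_weight(topo, 0) == 3.0
        assert np.isnan(dn.mean_outgoing_weight(topo, 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_percentile_matches_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        m = sp.random(n, n, density=0.3, random_state=seed,
                      data_rvs=lambda k: rng.uniform(0.1, 5, k)).tolil()
        m.setdiag(0)
        topo = topology_with_weights(n, m)
        rep = dn.detect_drivers_percentile(topo, 0.2)
        means = dn.mean_outgoing_weights(topo)
        ranked = np.flatnonzero(~np.isnan(means))
        order = sorted(ranked, key=lambda i: (-means[i], i))
        want = sorted(order[:int(round(0.2 * len(ranked)))])
        assert list(rep.driver_ids) == want
        assert np.all(means[rep.driver_ids] >= rep.threshold)

    def test_half_percent_of_4000_is_20(self):
        rng = np.random.default_rng(0)
        topo = dn.build_random_topology(4000, 0, 0.01, seed=1)
        topo.w["ee"].data[:] = rng.uniform(0.5, 2.0, topo.w["ee"].nnz)
        rep = dn.detect_drivers_percentile(topo, 0.005)
        assert rep.driver_ids.size == 20

    def test_ties_broken_towards_lower_ids(self):
        topo = topology_with_weights(10, np.ones((10, 10)) - np.eye(10))
        rep = dn.detect_drivers_percentile(topo, 0.2)
        assert list(rep.driver_ids) == [0, 1]

    def test_sd_method_all_equal_gives_empty(self):
        topo = topology_with_weights(10, np.ones((10, 10)) - np.eye(10))
        rep = dn.detect_drivers_sd(topo, 3.0)
        assert rep.driver_ids.size == 0

    def test_sd_method_finds_constructed_outlier(self):
        n = 50
        w = np.ones((n, n)) - np.eye(n)
        w[7, :] *= 30.0  # one cell far above mean + 5 SD
        np.fill_diagonal(w, 0)
        topo = topology_with_weights(n, w)
        rep = dn.detect_drivers_sd(topo, 3.0)
        assert list(rep.driver_ids) == [7]


class TestShuffleSurrogate:
    def test_weight_multiset_and_edges_preserved(self, small_topology):
        topo = small_topology.copy()
        rng = np.random.default_rng(5)
        topo.w["ee"].data[:] = rng.uniform(0, 3, topo.w["ee"].nnz)
        orig_sorted = np.sort(topo.w["ee"].data.copy())
        dn.shuffle_weight_surrogate(topo, n_shuffles=3, seed=1)
        assert np.array_equal(np.sort(topo.w["ee"].data), orig_sorted)

    def test_all_equal_weights_identical_curves(self, small_topology):
        orig, mean, sd = dn.shuffle_weight_surrogate(small_topology,
                                                     n_shuffles=5, seed=2)
        assert np.allclose(orig, mean)
        assert np.allclose(sd, 0.0)

    def test_clustered_weights_exceed_surrogate_top_quantile(self):
        # construct clustering: one cell's outgoing weights huge
        topo = dn.build_random_topology(100, 0, 0.2, seed=3)
        topo.w["ee"].data[:] = 1.0
        row = topo.w["ee"].tocoo().row
        topo.w["ee"].data[row == 0] = 15.0
        orig, mean, sd = dn.shuffle_weight_surrogate(topo, n_shuffles=50,
                                                     seed=4)
        assert orig[-1] > mean[-1] + 4 * sd[-1]


class TestSubgroupConnections:
    def test_complete_digraph(self):
        topo = topology_with_weights(
            25, np.ones((25, 25)) - np.eye(25))
        assert dn.count_subgroup_connections(topo, range(20)) == 380

    def test_empty_graph(self):
        topo = dn.Topology(30, 0)
        assert dn.count_subgroup_connections(topo, range(20)) == 0

    def test_matches_submatrix_oracle_and_permutation_invariance(self,
                                                                 small_topology):
        rng = np.random.default_rng(7)
        ids = rng.choice(100, 20, replace=False)
        got = dn.count_subgroup_connections(small_topology, ids)
        dense = small_topology.w["ee"].toarray() != 0
        want = sum(dense[a, b] for a in ids for b in ids if a != b)
        assert got == want
        assert dn.count_subgroup_connections(
            small_topology, ids[::-1]) == got

    def test_duplicate_ids_rejected(self, small_topology):
        with pytest.raises(ValueError):
            dn.count_subgroup_connections(small_topology, [1, 1, 2])

    def test_er_subgroups_match_analytic_expectation(self):
        rng = np.random.default_rng(11)
        counts = []
        for s in range(200):
            topo = dn.build_random_topology(200, 0, 0.02, seed=s)
            ids = rng.choice(200, 20, replace=False)
            counts.append(dn.count_subgroup_connections(topo, ids))
        counts = np.asarray(counts)
        sem = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 7.6) < 4 * sem


class TestSTA:
    def build_record_with_bursts(self, causal):
        """Group of 5 cells bursts every 500 ms; population rate steps up
        after each burst if causal."""
        rng = np.random.default_rng(8)
        duration = 60_000.0
        events = np.arange(500.0, duration - 500.0, 500.0)
        times, ids = [], []
        for t0 in events:
            for g in range(5):
                times.append(t0 + rng.uniform(0, 0.9))
                ids.append(g)
        # background population (cells 5..104): constant rate, plus burst
        # response after events when causal
        for i in range(5, 105):
            n = rng.poisson(duration / 1000.0 * 5.0)
            times.extend(rng.uniform(0, duration, n))
            ids.extend([i] * n)
            if causal:
                for t0 in events:
                    n2 = rng.poisson(2.0)
                    times.extend(t0 + rng.uniform(1.0, 50.0, n2))
                    ids.extend([i] * n2)
        t = np.asarray(times)
        order = np.argsort(t)
        return dn.SpikeRecord(t[order], np.asarray(ids)[order], 105, 0,
                              duration)

    def test_causal_bursts_give_asymmetric_sta(self):
        rec = self.build_record_with_bursts(causal=True)
        lags, sta, n = dn.synchrony_triggered_average(rec, range(5), k=5)
        assert n > 50
        post = sta[(lags > 0) & (lags <= 50)].mean()
        pre = sta[(lags < 0) & (lags >= -50)].mean()
        assert post > pre * 1.2

    def test_independent_group_sta_flat(self):
        rec = self.build_record_with_bursts(causal=False)
        lags, sta, n = dn.synchrony_triggered_average(rec, range(5), k=5)
        post = sta[(lags > 0) & (lags <= 50)].mean()
        pre = sta[(lags < 0) & (lags >= -50)].mean()
        base = sta.mean()
        assert abs(post - pre) < 0.2 * base

    def test_k_larger_than_group_gives_no_events(self):
        rec = self.build_record_with_bursts(causal=True)
        lags, sta, n = dn.synchrony_triggered_average(rec, range(5), k=6)
        assert n == 0 and lags.size == 0


class TestPSTH:
    def test_flat_for_stationary_poisson(self):
        rec = poisson_record(10.0, 200_000.0, n_neurons=50, seed=9)
        centers, rate = dn.psth(rec, 10.0, [100_000.0],
                                window=(-50_000.0, 50_000.0))
        assert rate.mean() == pytest.approx(10.0, rel=0.1)

    def test_empty_record_gives_zeros(self):
        rec = dn.SpikeRecord([], [], 10, 0, 1000.0)
        _, rate = dn.psth(rec, 1.0, [500.0])
        assert np.all(rate == 0)

    def test_single_alignment_equals_raw_binned_rate(self):
        rec = poisson_record(7.0, 1000.0, n_neurons=20, seed=10)
        centers, rate = dn.psth(rec, 50.0, [0.0], window=(0.0, 1000.0))
        counts, _ = np.histogram(rec.times, bins=np.arange(0, 1001, 50.0))
        assert np.allclose(rate, counts / (20 * 0.05))


class TestDistributionFits:
    def sample_pareto(self, alpha_mag, n, x_min, seed):
        rng = np.random.default_rng(seed)
        return x_min * rng.random(n) ** (-1.0 / (alpha_mag - 1.0))

    def test_powerlaw_exponent_recovery(self):
        x = self.sample_pareto(1.92, 100_000, 0.2, seed=1)
        fit = dn.fit_powerlaw_mle(x, upper_trim_fraction=0.0)
        assert fit.alpha == pytest.approx(-1.92, abs=0.05)

    def test_powerlaw_recovery_bias_across_seeds(self):
        errs = [dn.fit_powerlaw_mle(
            self.sample_pareto(1.92, 30_000, 0.2, seed=s),
            upper_trim_fraction=0.0).alpha + 1.92 for s in range(10)]
        assert abs(np.mean(errs)) < 0.03 * 1.92

    def test_trim_discards_strongest_samples(self):
        x = self.sample_pareto(1.92, 20_000, 0.2, seed=2)
        fit = dn.fit_powerlaw_mle(x, upper_trim_fraction=0.05)
        assert fit.upper_bound <= np.quantile(x, 0.9500001)

    def test_exponential_fits_worse_than_pareto(self):
        rng = np.random.default_rng(3)
        pareto = self.sample_pareto(1.92, 20_000, 0.2, seed=3)
        expo = rng.exponential(1.0, 20_000) + 0.2
        ks_p = dn.fit_powerlaw_mle(pareto, 0.0).ks_distance
        ks_e = dn.fit_powerlaw_mle(expo, 0.0).ks_distance
        assert ks_e > 2 * ks_p

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            dn.fit_powerlaw_mle(np.ones(10), 0.0)

    def test_lognormal_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(1.0, 0.5, 10_000)
        mu, sigma, ks, nz = dn.fit_lognormal(x)
        assert mu == pytest.approx(1.0, abs=0.05)
        assert sigma == pytest.approx(0.5, abs=0.05)
        assert nz == 0

    def test_lognormal_constant_sigma_zero(self):
        mu, sigma, ks, nz = dn.fit_lognormal(np.full(100, 3.0))
        assert sigma == 0.0 and mu == pytest.approx(np.log(3.0))

    def test_lognormal_zeros_excluded_and_counted(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.lognormal(0, 1, 1000), np.zeros(17)])
        *_, nz = dn.fit_lognormal(x)
        assert nz == 17

    def test_lognormal_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dn.fit_lognormal(np.zeros(10))
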