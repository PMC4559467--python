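"""Numba time-stepping kernel for the balanced-network simulation.

The (V, g_e, g_i) system is linear between spikes, so each dt step applies
the exact exponential propagator; thresholding, reset and same-step spike
delivery happen after the propagation.  STDP bookkeeping uses per-cell
eligibility traces; coincident pre/post spikes in one step are resolved
depression-first (a zero lag pair belongs to the depression branch).

All cadence logic (normalization every 100 ms, scaling every 50 ms) runs
on the *global* step counter so that chunked calls from Python are
seamless.
"""

import numpy as np
from numba import njit

# STDP amplitude modes
MODE_ADDITIVE = 0
MODE_PARTLY = 1
MODE_FULLY = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _amp_plus(mode, a_eff, w, w_max):
    if mode == MODE_FULLY:
        v = a_eff * (1.0 - w / w_max)
        return v if v > 0.0 else 0.0
    return a_eff


@njit(cache=True, inline="always")
def _amp_minus(mode, a_eff, w, w_max):
    if mode == MODE_PARTLY or mode == MODE_FULLY:
        return a_eff * (w / w_max)
    return a_eff


@njit(cache=True, fastmath=True)
def run_steps(
    # sizes / clock
    n_e, n_i, n_steps, step0,
    # exact-propagator constants
    a_m, a_e, a_i, k_e, k_i,
    E_L, V_thres, V_reset, ref_steps,
    # state (modified in place)
    V, ge, gi, ref,
    # drive
    drive, poisson_lam_total, poisson_w,
    # presynaptic-excitatory CSR over all N targets
    exc_indptr, exc_indices, exc_data,
    # presynaptic-inhibitory CSR over all N targets
    inh_indptr, inh_indices, inh_data,
    # E-E plasticity
    ee_on, ee_mode, ee_ap, ee_am, ee_wmax, ee_dec_p, ee_dec_m,
    x_pre, x_post, lx_pre, lx_post, ee_cptr, ee_cpos, ee_crow,
    # I-E plasticity (additive)
    ie_on, ie_ap, ie_am, ie_wmax, ie_dec_p, ie_dec_m,
    y_pre, y_post, ly_pre, ly_post, ie_cptr, ie_cpos, ie_crow,
    # normalization
    norm_on, norm_every, ee_target_sum,
    # slow scaling
    scal_on, scal_every, gamma, nu0, bin_seconds, window_bins,
    cur_counts, rate_counts, rate_totals, rate_state,
    # spike recording
    record_from, spike_step, spike_id,
):
    """Advance the network ``n_steps`` steps.

    Eligibility traces decay lazily: each per-cell trace carries the
    global step of its last update (lx_*, ly_*) and is decayed on demand,
    which keeps the per-step cost at O(N) membrane work plus O(spikes x
    degree) synaptic work.

    Returns (n_recorded, total_spikes, ok) where ok=0 flags a recording
    buffer overflow (recording stops, dynamics continue) and ok=-1 a
    non-finite membrane potential.
    """
    n = n_e + n_i
    cap = spike_step.shape[0]
    n_rec = 0
    total_spikes = 0
    ok = 1
    spk_buf = np.empty(n, dtype=np.int64)

    for t_rel in range(n_steps):
        g_step = step0 + t_rel + 1  # global step completed after this iteration

        # exact propagation of the linear (V, g_e, g_i) system, with
        # refractory clamp and threshold detection fused into one pass
        # (spike delivery only touches g, i.e. the *next* step's current)
        n_spk = 0
        for i in range(n):
            rest = E_L + drive[i]
            v = rest + (V[i] - rest) * a_m + k_e * ge[i] - k_i * gi[i]
            ge[i] *= a_e
            gi[i] *= a_i
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = V_reset
            elif v >= V_thres:
                if not np.isfinite(v):
                    return n_rec, total_spikes, -1
                V[i] = V_reset
                ref[i] = ref_steps
                spk_buf[n_spk] = i
                n_spk += 1
            else:
                V[i] = v
        total_spikes += n_spk

        # external Poisson events (unit-weight excitatory synapse per cell)
        if poisson_lam_total > 0.0:
            n_ev = np.random.poisson(poisson_lam_total)
            for _ in range(n_ev):
                ge[np.random.randint(0, n)] += poisson_w

        if n_spk == 0:
            if norm_on and g_step % norm_every == 0:
                _normalize_pass(n_e, exc_data, ee_cptr, ee_cpos,
                                ee_target_sum, ee_wmax)
            if scal_on and g_step % scal_every == 0:
                _scaling_pass(n_e, exc_data, ee_cptr, ee_cpos, ee_wmax,
                              gamma, nu0, bin_seconds, window_bins,
                              cur_counts, rate_counts, rate_totals,
                              rate_state)
            continue

        if t_rel >= record_from:
            if n_rec + n_spk <= cap:
                for k in range(n_spk):
                    spike_step[n_rec] = g_step
                    spike_id[n_rec] = spk_buf[k]
                    n_rec += 1
            else:
                ok = 0

        # postsynaptic trace increments first: zero-lag pairs must depress
        for k in range(n_spk):
            i = spk_buf[k]
            if i < n_e:
                if ee_on:
                    d = g_step - lx_post[i]
                    if d > 0:
                        x_post[i] *= ee_dec_m ** d
                        lx_post[i] = g_step
                    x_post[i] += 1.0
                if ie_on:
                    d = g_step - ly_post[i]
                    if d > 0:
                        y_post[i] *= ie_dec_m ** d
                        ly_post[i] = g_step
                    y_post[i] += 1.0
                if scal_on:
                    cur_counts[i] += 1

        # presynaptic events: transmit with the current weight, then depress
        for k in range(n_spk):
            i = spk_buf[k]
            if i < n_e:
                for j in range(exc_indptr[i], exc_indptr[i + 1]):
                    tgt = exc_indices[j]
                    w = exc_data[j]
                    ge[tgt] += w
                    if ee_on and tgt < n_e:
                        d = g_step - lx_post[tgt]
                        if d > 0:
                            x_post[tgt] *= ee_dec_m ** d
                            lx_post[tgt] = g_step
                        w -= _amp_minus(ee_mode, ee_am, w, ee_wmax) * x_post[tgt]
                        if w < 0.0:
                            w = 0.0
                        elif w > ee_wmax:
                            w = ee_wmax
                        exc_data[j] = w
            else:
                m = i - n_e
                for j in range(inh_indptr[m], inh_indptr[m + 1]):
                    tgt = inh_indices[j]
                    w = inh_data[j]
                    gi[tgt] += w
                    if ie_on and tgt < n_e:
                        d = g_step - ly_post[tgt]
                        if d > 0:
                            y_post[tgt] *= ie_dec_m ** d
                            ly_post[tgt] = g_step
                        w -= ie_am * y_post[tgt]
                        if w < 0.0:
                            w = 0.0
                        elif w > ie_wmax:
                            w = ie_wmax
                        inh_data[j] = w

        # postsynaptic events: potentiate incoming plastic synapses
        for k in range(n_spk):
            i = spk_buf[k]
            if i < n_e:
                if ee_on:
                    for j in range(ee_cptr[i], ee_cptr[i + 1]):
                        pre = ee_crow[j]
                        d = g_step - lx_pre[pre]
                        if d > 0:
                            x_pre[pre] *= ee_dec_p ** d
                            lx_pre[pre] = g_step
                        if x_pre[pre] == 0.0:
                            continue
                        pos = ee_cpos[j]
                        w = exc_data[pos]
                        w += _amp_plus(ee_mode, ee_ap, w, ee_wmax) * x_pre[pre]
                        if w < 0.0:
                            w = 0.0
                        elif w > ee_wmax:
                            w = ee_wmax
                        exc_data[pos] = w
                if ie_on:
                    for j in range(ie_cptr[i], ie_cptr[i + 1]):
                        pre = ie_crow[j]
                        d = g_step - ly_pre[pre]
                        if d > 0:
                            y_pre[pre] *= ie_dec_p ** d
                            ly_pre[pre] = g_step
                        if y_pre[pre] == 0.0:
                            continue
                        pos = ie_cpos[j]
                        w = inh_data[pos]
                        w += ie_ap * y_pre[pre]
                        if w < 0.0:
                            w = 0.0
                        elif w > ie_wmax:
                            w = ie_wmax
                        inh_data[pos] = w

        # presynaptic trace increments after the updates (zero-lag pairs
        # must not potentiate)
        for k in range(n_spk):
            i = spk_buf[k]
            if i < n_e:
                if ee_on:
                    d = g_step - lx_pre[i]
                    if d > 0:
                        x_pre[i] *= ee_dec_p ** d
                        lx_pre[i] = g_step
                    x_pre[i] += 1.0
            elif ie_on:
                m = i - n_e
                d = g_step - ly_pre[m]
                if d > 0:
                    y_pre[m] *= ie_dec_p ** d
                    ly_pre[m] = g_step
                y_pre[m] += 1.0

        # incoming E-E weight normalization
        if norm_on and g_step % norm_every == 0:
            _normalize_pass(n_e, exc_data, ee_cptr, ee_cpos, ee_target_sum,
                            ee_wmax)

        # slow synaptic scaling
        if scal_on and g_step % scal_every == 0:
            _scaling_pass(n_e, exc_data, ee_cptr, ee_cpos, ee_wmax,
                          gamma, nu0, bin_seconds, window_bins,
                          cur_counts, rate_counts, rate_totals, rate_state)

    return n_rec, total_spikes, ok


@njit(cache=True, inline="always")
def _normalize_pass(n_e, exc_data, ee_cptr, ee_cpos, ee_target_sum, ee_wmax):
    for t in range(n_e):
        lo = ee_cptr[t]
        hi = ee_cptr[t + 1]
        if hi == lo:
            continue
        s = 0.0
        for j in range(lo, hi):
            s += exc_data[ee_cpos[j]]
        if s <= 0.0:
            continue
        f = ee_target_sum[t] / s
        for j in range(lo, hi):
            w = exc_data[ee_cpos[j]] * f
            if w > ee_wmax:
                w = ee_wmax
            exc_data[ee_cpos[j]] = w


@njit(cache=True, inline="always")
def _scaling_pass(n_e, exc_data, ee_cptr, ee_cpos, ee_wmax, gamma, nu0,
                  bin_seconds, window_bins, cur_counts, rate_counts,
                  rate_totals, rate_state):
    head = rate_state[0]
    nfill = rate_state[1]
    if nfill == window_bins:
        for t in range(n_e):
            rate_totals[t] -= rate_counts[head, t]
    else:
        nfill += 1
    for t in range(n_e):
        rate_counts[head, t] = cur_counts[t]
        rate_totals[t] += cur_counts[t]
        cur_counts[t] = 0
    rate_state[0] = (head + 1) % window_bins
    rate_state[1] = nfill
    elapsed = nfill * bin_seconds
    for t in range(n_e):
        nu = rate_totals[t] / elapsed
        fac = gamma * (nu - nu0) * bin_seconds
        if fac == 0.0:
            continue
        for j in range(ee_cptr[t], ee_cptr[t + 1]):
            pos = ee_cpos[j]
            w = exc_data[pos]
            w -= fac * w * w
            if w < 0.0:
                w = 0.0
            elif w > ee_wmax:
                w = ee_wmax
            exc_data[pos] = w


@njit(cache=True)
def fan_in_steps(
    n_steps, n_syn, rate_p, w,
    a_m, a_e, k_e, E_L, V_thres, V_reset, ref_steps, drive,
    ap, am, dec_p, dec_m, w_max,
    norm_every, target_sum,
    rec_every, w_out, seed,
):
    """Poisson fan-in onto one LIF cell: all-to-all STDP + normalization.

    ``rate_p`` holds per-source spike probabilities per step; ``w`` the
    synaptic weights (modified in place).  Records weight snapshots into
    ``w_out`` every ``rec_every`` steps.  Returns the number of
    postsynaptic spikes.
    """
    np.random.seed(seed)
    V = V_reset
    g = 0.0
    ref = 0
    x_pre = np.zeros(n_syn)
    x_post = 0.0
    n_post = 0
    rec = 0
    spk = np.empty(n_syn, dtype=np.int64)
    for step in range(n_steps):
        x_post *= dec_m
        for j in range(n_syn):
            x_pre[j] *= dec_p
        rest = E_L + drive
        V = rest + (V - rest) * a_m + k_e * g
        g *= a_e
        n_spk = 0
        for j in range(n_syn):
            if np.random.random() < rate_p[j]:
                spk[n_spk] = j
                n_spk += 1
        post_spiked = False
        if ref > 0:
            ref -= 1
            V = V_reset
        elif V >= V_thres:
            V = V_reset
            ref = ref_steps
            post_spiked = True
            n_post += 1
            x_post += 1.0
        for k in range(n_spk):
            j = spk[k]
            g += w[j]
            wj = w[j] - am * x_post
            if wj < 0.0:
                wj = 0.0
            elif wj > w_max:
                wj = w_max
            w[j] = wj
        if post_spiked:
            for j in range(n_syn):
                wj = w[j] + ap * x_pre[j]
                if wj < 0.0:
                    wj = 0.0
                elif wj > w_max:
                    wj = w_max
                w[j] = wj
        for k in range(n_spk):
            x_pre[spk[k]] += 1.0
        if (step + 1) % norm_every == 0:
            s = 0.0
            for j in range(n_syn):
                s += w[j]
            if s > 0.0:
                f = target_sum / s
                for j in range(n_syn):
                    wj = w[j] * f
                    if wj > w_max:
                        wj = w_max
                    w[j] = wj
        if (step + 1) % rec_every == 0 and rec < w_out.shape[0]:
            for j in range(n_syn):
                w_out[rec, j] = w[j]
            rec += 1
    return n_post


@njit(cache=True)
def two_neuron_frozen_steps(
    n_steps, lam_in, jump, w,
    a_m, E_L, V_thres, V_reset, ref_steps,
    dec_stdp, ap, am,
    v_every, v_samples, seed,
):
    """Two Poisson-driven LIF cells A -> B with a frozen delta synapse.

    Nearest-neighbour STDP updates are accumulated but never applied
    (the weight stays at ``w``): each presynaptic spike depresses with
    the nearest preceding postsynaptic spike and potentiates with the
    nearest following one (delivery is one step delayed, so a directly
    triggered postsynaptic spike pairs at lag dt).  External input is
    ignored while a cell is refractory (the delta analogue of clamping).

    Returns (n_pre, n_post, accumulated_dw, n_v_samples); subthreshold
    voltage samples of B are written into ``v_samples`` every
    ``v_every`` steps.
    """
    np.random.seed(seed)
    VA = V_reset
    VB = V_reset
    refA = 0
    refB = 0
    z = 0.0              # decayed sum over presynaptic spikes since last post
    last_post = -1
    pending = 0.0        # synaptic deflection delivered to B next step
    dw = 0.0
    n_pre = 0
    n_post = 0
    n_v = 0
    step_exp = dec_stdp  # per-step decay of the pairing kernel
    for step in range(n_steps):
        z *= step_exp
        VA = E_L + (VA - E_L) * a_m
        VB = E_L + (VB - E_L) * a_m
        if refA == 0:
            kA = np.random.poisson(lam_in)
            if kA > 0:
                VA += jump * kA
        if refB == 0:
            kB = np.random.poisson(lam_in)
            if kB > 0:
                VB += jump * kB
            VB += pending
        pending = 0.0
        # postsynaptic cell first: a just-delivered presynaptic deflection
        # can trigger it this step (lag dt)
        if refB > 0:
            refB -= 1
            VB = V_reset
        elif VB >= V_thres:
            VB = V_reset
            refB = ref_steps
            n_post += 1
            dw += ap * z
            z = 0.0
            last_post = step
        else:
            if v_every > 0 and step % v_every == 0 and n_v < v_samples.shape[0]:
                v_samples[n_v] = VB
                n_v += 1
        if refA > 0:
            refA -= 1
            VA = V_reset
        elif VA >= V_thres:
            VA = V_reset
            refA = ref_steps
            n_pre += 1
            if last_post >= 0:
                dw -= am * dec_stdp ** (step - last_post)
            z += 1.0
            pending = w
    return n_pre, n_post, dw, n_v
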