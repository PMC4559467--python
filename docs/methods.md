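# Model and methods

## Network model

Leaky integrate-and-fire membranes follow

    tau_m dV/dt = -(V - E_L - D) + I_e - I_i,

with tau_m = 20 ms, E_L = -60 mV, threshold -50 mV, reset -60 mV and an
absolute refractory period of 2 ms during which V is clamped at reset
(synaptic traces keep integrating). D is the external drive: by default a
constant 11 mV depolarization (relaxation target E_L + 11 mV, i.e. just
above threshold, so the network is inhibition-stabilized), optionally an
equivalent per-cell Poisson bombardment through a unit-weight excitatory
synapse at rate D/(c_e tau_e) = 2200 Hz.

Synaptic currents are current-based with exponential kernels: a
presynaptic spike increments the target's trace g by the synaptic weight
w, and the current is c_e g_e (c_e = 1 mV) minus |c_i| g_i
(c_i = -9 mV); tau_e = 5 ms, tau_i = 10 ms. Inhibition is
hyperpolarizing: the calibration anchor is the unit-weight PSP pair
+0.157 mV / -2.25 mV given by the closed form
w |c| tau_s/(tau_m - tau_s) (e^(-t/tau_m) - e^(-t/tau_s)) at its peak.
Weights are dimensionless in [0, w_max] with w_max = 20 (excitatory)
and 5 (inhibitory).

Wiring: directed, mono-synaptic, no self-edges. Constructors: (i)
Erdős–Rényi with p = 0.02 for all four connection classes (base network
4000 E + 1000 I); (ii) homogeneous in-degree (every cell draws exactly
k_e excitatory and k_i inhibitory presynaptic partners; out-degrees stay
random); (iii) topographic wiring on the unit torus with
P(connect) = eps * exp(-d^2/(2 sigma^2)) of the presynaptic cell's class
(excitatory eps = 0.2, sigma = 0.1; inhibitory eps = 0.8, sigma = 0.05),
excitatory positions uniform, inhibitory uniform or on a regular lattice
with half-cell offset.

## Integration scheme

Clock-driven, dt = 0.1 ms by default. Between spikes the (V, g_e, g_i)
system is linear, so each step applies the exact exponential propagator;
an isolated neuron's trajectory matches the analytic solution to float
precision at any dt. Thresholding happens after propagation; spikes are
delivered to the targets' traces within the same step (zero transmission
delay — delivered current first affects the membrane at the next step, so
a directly triggered postsynaptic spike follows its cause by one step).
The refractory clamp lasts ceil(tau_ref/dt) steps. The engine aborts
with a diagnostic if the mean population rate exceeds a ceiling (default
100 Hz) over a 10 s window, or if the state becomes non-finite.

## Plasticity

STDP is pair-based with exponential kernels and all-to-all spike
pairings, realized online through per-cell eligibility traces; the trace
algebra is exactly equivalent to summing the kernel over all spike pairs
(verified against a brute-force oracle). Zero-lag pairs belong to the
depression branch: within one step, postsynaptic trace increments are
applied before depression-on-pre, and potentiation-on-post reads the
presynaptic trace before its increment. A transmitted spike uses the
weight before that event's depression.

* E-E: additive by default, A+ = 1e-3, A- = 1.05 A+, tau± = 20 ms;
  amplitudes are multiplied by w_max (effective 0.02 / 0.021). Partly
  multiplicative (depression proportional to w) and fully multiplicative
  (potentiation proportional to w_max - w, depression to w) variants are
  provided as configurable amplitude functions; their exact published
  forms live in an unavailable supplement, so they follow the standard
  forms from the literature they cite and only qualitative behavior
  should be read into them.
* I-E: additive only, A- = 1e-3, A+ = 4 A- (effective 0.005 / 0.02);
  the kernel integral is positive, so inhibition onto fast-firing cells
  grows — the stabilizing negative feedback.
* Homeostasis at E-E, postsynaptic site: every 100 ms each excitatory
  cell's incoming weight vector is rescaled so its sum equals
  in-degree × 1 (proportions preserved); clipping to [0, w_max] is
  applied after rescaling, so a cell whose strongest synapse is pinned at
  the cap can fall short of the exact target by the clipped excess (at
  reduced scale this affects <1% of cells; a redistribution scheme would
  restore exactness but is not the model's rule). Cells with zero
  incoming weight sum are skipped with a warning. The slow alternative,
  dw/dt = -gamma (nu - nu_0) w^2 with gamma = 1e-6 and nu_0 = 0 Hz, runs
  every 50 ms with rates estimated over a trailing 100 s window.

Synapses silenced by plasticity (weight exactly 0) remain structural
edges: they still count in degrees, in normalization targets, and in
subgroup connection counts.

## Experiments

**Plastic transient.** The network runs with full plasticity until the
E-E weight distribution stops moving: Kolmogorov–Smirnov distance
between snapshots 10 minutes apart below 0.01, or a hard duration cap
(the published transient is ~5 h; the reduced-scale configuration used
throughout the test suite is 800 E + 200 I, p = 0.02, 30 biological
minutes, which preserves the qualitative self-organization: heavy-tailed
E-E weights, fast-firing driver cells, rich-club driver subnetworks).

**Driver detection.** Per-cell mean outgoing E-E weight (structural
out-degree in the denominator; zero-out-degree cells excluded). Driver
group = top 0.5% (ties to lower ids) or cells above mean + 3 SD.
Shuffle surrogates permute weights over the fixed edge set to show the
clustering is not a sampling artifact.

**Stimulation.** Two 0.5 ms pulses of a very strong current
(3000 mV-equivalent, guaranteeing a threshold crossing within one step
from any subthreshold potential), onsets 2 ms apart so the refractory
period has elapsed; a trial proceeds only if no target is refractory at
onset, and every target then fires exactly two spikes 2 + O(dt) ms
apart. Trials are separated by exponentially distributed washouts (mean
2 s) and plasticity is frozen while probing. Readout: excitatory
population PSTH (1 ms bins) and the post/pre rate ratio over ±100 ms.

**Reduced validation models.**

* *Inhibitory pair*: postsynaptic cell with linear subthreshold rise at
  rate nu_0 (V_thres - V_rest) per second (it fires at nu_0 without
  inhibition), presynaptic Poisson cell, delta synapse subtracting w
  (unclamped, matching the derivation's linear model), nearest-neighbour
  pairing. The stationary weight matches
  w_stat = nu_0 tau dV ln(A+/A-) in the derivation's regime of at most
  one presynaptic spike per postsynaptic interval; validation runs use a
  1 Hz presynaptic rate for that reason (at 5 Hz multi-spike
  interactions bias the equilibrium by 10–20%).
* *Fan-in competition*: 80 Poisson inputs through plastic E-E synapses
  onto one LIF cell under incoming-sum normalization; 10 inputs at
  25 Hz, 70 at 5 Hz. The background drive default (6 mV) puts the
  postsynaptic cell at the ~5 Hz operating point, where the fast group
  reliably wins the competition; at much higher postsynaptic rates the
  depression-dominated additive rule reverses the outcome.
* *Frozen-weight excitatory pair*: two LIF cells bombarded by 1650
  delta synapses (1 Hz, 0.5 mV each; the cells are then mean-driven at
  ~49 Hz), connected by a frozen delta synapse of strength w (mV);
  nearest-neighbour STDP updates are accumulated but not applied,
  yielding the mean update per presynaptic spike at fixed w, plus the
  postsynaptic rate (for the linear rate-vs-weight fit) and subthreshold
  voltage samples (for the membrane-potential distribution).

## Mean-field theory

Inhibitory strand: delay d_w = w/(nu_0 dV), stationary weight
w_stat = nu_0 tau dV ln(A+/A-) (the exact root of the averaged
nearest-neighbour update), compensated rate
nu = nu_0/(1 + tau nu_inh ln(A+/A-)) — extra drive is never fully
compensated.

Excitatory strand: the mean update per presynaptic spike combines (i)
the spike-triplet pair contribution over a postsynaptic interval T, with
the next postsynaptic spike shifted back by
s = dr/(r(r + dr)), dr = (fitted slope) × w, and the interval tail
(T - s, T] excluded; (ii) T averaged over an inverse-Gaussian ISI
distribution with mu = 1/nu and lambda = 0.75/nu (the estimate varies by
<5% over lambda in [0.5/nu, 1/nu]); (iii) a direct-trigger term
P_fire(w) A+ e^(-tau_syn/tau) with P_fire the membrane-potential mass
within w of threshold (empirical histogram or the standard
diffusion-approximation stationary density; the two agree to KS < 0.05
on the validation drive). The ISI-density integral is multiplied by nu:
a presynaptic spike lands in an interval with length-biased probability,
which makes the triplet average a per-presynaptic-spike quantity of
consistent units. Quadrature is adaptive up to the 1 - 1e-6 ISI
quantile at relative tolerance 1e-6. tau_syn defaults to the engine dt.
Theory-side weights are in mV (delta-synapse convention); network
weights are dimensionless, and any conversion goes through the unit-PSP
calibration explicitly.

Known limitation: at strongly mean-driven operating points (trigger
probabilities of order 0.3) the direct-trigger term overlaps with the
tail of the pair integral — the excluded window s is much shorter than
the actual trigger zone (~P_fire × T) — so the estimate overshoots the
simulated mean update there by up to a factor ~2, although the sign
structure (depression-dominated at w = 0, a single crossing to net
potentiation at a threshold weight) is robust. Component-wise, the
depression term and the non-trigger potentiation match the simulation
to ~1% once the trigger zone is accounted for.

## Statistics

Rates are spike counts over explicit windows (the final 100 s of a run
by default); ISI CV requires ≥3 spikes. The power-law fit is a
continuous truncated MLE: the strongest 5% of samples are discarded,
the lower bound x_min is chosen over a quantile grid by minimizing the
KS distance to the fitted truncated power law (exponent re-estimated by
likelihood maximization for each candidate), and the density exponent
is reported with its negative sign. Log-normal fits are MLE on logs
(zeros excluded and counted). Synchrony-triggered averages use 1 ms
bins; events closer than one half-width collapse to the first, and
events whose window leaves the record are dropped.

## Randomness and reproducibility

Every protocol takes a single seed; per-component substreams derive from
it by mixing with a stable component tag (CRC32 into a SeedSequence), so
toggling one component never perturbs another's stream. Runs are
bit-reproducible for a given seed. All file output (MatrixMarket
weights, TSV spikes/states/trajectories, JSON manifests with SHA-256
checksums) is locale-independent text.

## What the reduced-scale tests do and do not show

The reduced network (800+200, 30 min) reproduces the mechanism — heavy
tails, driver emergence via local under-inhibition, rich-club formation,
the causal dynamical impact of driver synchrony — but not the published
full-scale magnitudes (power-law exponent -1.92 at x_min 0.205, 25 Hz
driver rates, the 12.14-connection driver subnetworks), which require
~5 h of biological time at N = 5000–10000; those runs are supported
through the same API and config but are not part of the test suite. Two
full-scale claims did not reproduce at any tested scale and are
documented as red in the test suite: the homogeneous-in-degree network's
weights spread well beyond a delta peak (additive STDP plus
multiplicative renormalization is intrinsically unstable per cell, even
though no driver cells emerge there, which is the claim that matters
downstream), and the excitatory mean-field estimate does not track the
frozen-weight simulation within its (very small) trial SD at the
mean-driven operating point, for the trigger-zone reason above.
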