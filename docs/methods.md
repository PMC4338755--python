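# Methods

This note documents the models, numerical conventions, and design choices
behind `connectosim`, and states what the synthetic study conditions do and
do not establish about real data.

## Dynamical mean-field model

Each of the N nodes is a neural population reduced to a single average
synaptic gating variable S_i ∈ [0, 1]:

    dS_i/dt = -S_i/τ_S + (1 - S_i) γ H(x_i) + σ v_i(t)
    x_i     = w J_N S_i + G J_N Σ_j C_ij S_j + I_0 + applied_i(t)
    H(x)    = (a x - b) / (1 - exp(-d (a x - b)))

| symbol | meaning | default | unit |
|---|---|---|---|
| w | local recurrent excitation | 0.9 | – |
| a | input–output gain | 270 | Hz/nA |
| b | input–output threshold | 108 | Hz |
| d | input–output curvature | 0.154 | s |
| γ | kinetic parameter | 0.641 | – |
| τ_S | synaptic time constant | 0.1 | s |
| J_N | synaptic coupling | 0.2609 | nA |
| I_0 | overall external input | 0.3 | nA |
| σ | noise amplitude | study-dependent (0.01–0.1) | – |
| G | global coupling | calibrated per connectome | – |

Conventions worth stating explicitly:

- **Coupling sign.** The network term is excitatory (+G J_N Σ C_ij S_j) by
  default. Some printed forms of this reduced model carry a minus sign on
  the coupling term; with fiber-density matrices and these parameters an
  inhibitory coupling cannot produce the phenomena this package studies
  (a coupling-driven high-firing attractor, lesions that reduce network
  firing), so the excitatory convention is the default and
  `MeanFieldParams.coupling_sign = -1` exposes the literal alternative.
- **γ is dimensionless.** Parameter tables sometimes attach seconds to γ;
  dimensional consistency of the gating equation (1/s on both sides with
  H in Hz) requires γ dimensionless when τ_S is in seconds.
- **Reported "firing rate"** is H(x_i(t)) evaluated at sample times from the
  sampled state — the model's population rate, not a spike count.

## Numerics

- **Integration** is Euler–Maruyama: S += dt·drift + σ·√dt·ξ with ξ i.i.d.
  standard normal. The √dt scaling treats σ v_i(t) as white noise on
  dS/dt; `SimulationConfig(noise_scaling="per_step")` instead adds σ·ξ per
  step for the discrete-noise reading. Default dt = 0.1 ms, sampled every
  1 ms; a 10 s run emits exactly 10,000 samples (sampling intervals must be
  integer multiples of dt, checked).
- **Clamping.** S is clamped (not reflected) to [0, 1] after every step;
  S is a channel-open fraction and large σ would otherwise leave its
  domain. Clamping is on by default and switchable.
- **Transfer-function singularity.** H has a removable singularity at
  a·x = b; within |d·(a·x−b)| < 1e-8 the second-order expansion
  1/d + (a·x−b)/2 is used. H is total, finite and non-negative on all
  finite inputs (tested against a 50-digit arbitrary-precision oracle).
- **Noise streams.** One counter-based Philox stream per run, seeded from
  the configuration; each step draws an N-vector (node i reads element i),
  so results are independent of vectorization order and bit-reproducible.
  The ensemble integrator (`meanfield_window_means`) advances many
  (σ, seed) runs simultaneously against one coupling matrix but gives each
  column its own stream — its output is bit-identical to running each
  configuration alone, which is tested.
- **Stimulation windows** are half-open [t_on, t_off) and snapped once to
  integration-step indices, so window-boundary decisions are integer
  comparisons, immune to float-grid drift.
- **Initial condition** defaults to S_i(0) = 0.001 everywhere: runs start
  near the low-firing state and any transition to the high-firing attractor
  is part of the simulated dynamics.
- **Degenerate inputs.** Non-finite states abort with the failing step
  reported; empty connectomes read/write correctly; a lesioned (uncoupled)
  node integrates exactly like an isolated single-node model, which is
  tested against that reduction.

## Coupling calibration

`calibrate_g` places the network at the edge of the bifurcation where the
low-firing state loses stability: with σ = 0 and S(0) = 0.001, a trial G is
classified as destabilizing when the node-mean rate over the last 20% of a
4 s run exceeds r_low = 20 Hz — a threshold sitting between the low branch
(a few Hz) and the high branch (>150 Hz), so the classification is not
sensitive to its exact value. Bisection brackets the smallest destabilizing
G to a tolerance (default 0.02) and returns the bracket midpoint; an
optional margin subtracts a safety offset. A scan range that does not
bracket a stability change (e.g. an uncoupled network) is an error, not a
silent extrapolation. On the default synthetic connectome the calibrated
coupling comes out near G ≈ 0.5; its value scales inversely with the row
sums of C and is therefore dataset-specific.

## Synthetic connectome

The generator emulates the *shape* of an averaged human diffusion-imaging
connectome so that every experiment runs without the (non-redistributable)
empirical dataset:

- 998 nodes under the built-in 66-region atlas; coordinates are region
  centroids sampled in a ±(60, 80, 55) mm ellipsoid (right hemisphere
  x > 0, left x < 0) with 5 mm Gaussian node jitter;
- intra-region pairs connect with probability 0.30 (regions are modules);
- inter-region pairs connect with probability proportional to
  exp(−distance/40 mm), the canonical exponential falloff of fiber density
  with distance, normalized analytically so the expected unordered pair
  count equals the 17,000-pair target (a configuration whose expectation
  misses the target by >10% is rejected);
- nodes in the posterior structural core (PC, PCUN, CUN, PARC, ISTC, SP,
  both hemispheres) get a ×2 endpoint factor on inter-region connection
  probability. This reproduces the hub property of real cortical
  connectomes in which a posterior-medial focal lesion removes a
  disproportionate share of connections relative to an equally sized
  random lesion (on the default network: 11.5% vs ≈10% of pairs for 52
  clustered vs 50 scattered nodes);
- weights are lognormal(0, 1), max-normalized into (0, 1].

What the generator does **not** emulate: the empirical degree sequence and
weight–distance joint distribution, callosal (inter-hemispheric) topology,
and real Talairach geometry. Consequences observed on the synthetic
network: the calibrated coupling (~0.5) is smaller than values quoted for
empirical matrices (row-sum scale differs); the high-firing attractor sits
near 61 Hz per node at σ = 0.07 rather than ~40 Hz; and noise suppression
of total firing, while strictly monotone, is shallow — the synthetic
network ignites collectively and noise mainly shaves the saturated rate,
where heterogeneous empirical networks keep many near-threshold nodes whose
firing collapses with noise. Passing the qualitative tests here shows the
mechanisms are present, not that empirical magnitudes are reproduced; the
empirical reproductions live in a validation suite that activates when a
real connectome is placed at `data/hagmann_dsi.graphml`.

## Lesions, stimulation, analyses

- **Lesion = zeroed rows and columns**, nodes retained. This keeps node
  indexing stable across conditions (ΔFR maps are defined node-by-node)
  and makes re-application idempotent. Focal lesions take whole named
  regions; diffuse lesions sample nodes uniformly without replacement,
  seeded. `lesion_connection_fraction` counts unordered nonzero pairs with
  a lesioned endpoint over all unordered nonzero pairs (count mode) or the
  same ratio on summed weights (weight mode) — shares quoted against
  directed-entry denominators are half the count-mode value.
- **Stimulation** adds a constant signed current to a node set over a
  window; multiple stimulations compose additively. The default template
  amplitude is −0.1 nA over the first 5 s. On the near-critical synthetic
  network an inhibitory pulse on the structural core gates the collective
  ignition itself, so during-vs-after rate differences are large (tens of
  Hz network-wide) and the post-release return to baseline is a slow
  re-ignition (hundreds of ms, seed-dependent) rather than a local ~40 ms
  relaxation — a regime difference, documented rather than tuned away.
- **Windowed firing summaries** average sampled rates per node over a
  window, by convention the last 2 s of a run (both endpoints' samples
  included); totals sum non-lesioned nodes. ΔFR is the per-node difference
  of two summaries with matched windows; stimulation efferent maps compare
  2 s averages after vs before the release.
- **Return to baseline** is the first time after the perturbation ends at
  which the node-averaged rate stays within k_sd (default 2) baseline
  standard deviations of the baseline mean for hold_ms (default 20 ms)
  consecutive samples, with the baseline mean/sd taken from the last 2 s of
  a matched unperturbed run (same seed, removing noise-floor bias). The
  detection is a declared convention: latencies shrink as k_sd grows
  (tested monotone) and the defaults make the analytic exponential-
  relaxation case exact to one sample. A trace that never re-enters the
  band yields NaN, not an exception.

## Graph queries

Edge lengths for pathfinding invert the weights: ℓ = 1/w (default, the
standard convention for fiber-density matrices) or ℓ = −log(w/w_max).
Dijkstra is implemented directly because ties in total length are broken
deterministically by the lexicographically smallest node sequence — a
reproducibility guarantee off-the-shelf implementations do not make; it is
cross-checked against exhaustive path enumeration on small fixtures.
Efferent-edge bookmarking returns each unordered boundary edge once, sorted.

## Problem sizes

The shipped study conditions are 998-node connectomes integrated for 10 s
at dt = 0.1 ms (100,000 steps), with 5 seeds per noise level for the
stochastic comparisons and bisection to 0.02 on the coupling. The ensemble
integrator advances all (σ, seed) columns of a scan in one pass; a full
noise scan (20 runs) completes in roughly a minute and the complete
acceptance pipeline in a few minutes on one CPU.

## Known limitations

- No haemodynamic (BOLD) forward model, spiking backend, plasticity, or
  real-time interaction loop; no community detection or other
  graph-measure suites beyond paths and efferents.
- Directed connectomes are out of scope (tractography is undirected);
  asymmetric input is either rejected or symmetrized by averaging.
- `mirror_hemispheres` requires equal-sized, range-aligned hemisphere
  blocks; the built-in atlas (500 R / 498 L nodes) cannot be mirrored and
  the operation targets custom symmetric parcellations.
- The noise-suppression and lesion-resilience findings on the synthetic
  network are qualitative reproductions under emulated conditions; their
  magnitudes are not calibrated to any empirical dataset.
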