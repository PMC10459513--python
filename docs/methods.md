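# Methods

## Model overview

`spikewire` simulates a three-layer spiking network for 28×28 grayscale
image classification, trained without labels:

1. **Input layer** (784 neurons). Each pixel drives one Poisson spike
   train at rate = intensity/2 Hz (0–127.5 Hz), realized as a Bernoulli
   draw per 1 ms timestep (p ≤ 0.1275). A presentation lasts 350 ms,
   followed by a 150 ms rest interval.
2. **First layer** (N leaky integrate-and-fire neurons). Fully connected
   from the input through the plastic matrix `W_in` (STDP). Membrane
   dynamics: τ_m du/dt = −(u − u_rest) + R·I, explicit Euler, dt = 1 ms;
   τ_m = 20 ms, u_rest = −65 mV, threshold −40 mV, reset to rest, 5 ms
   refractory period during which the membrane is clamped at rest. An
   optional adaptive threshold offset (+0.05 mV per spike, decay constant
   1e7 ms) implements slow homeostasis.
3. **Second layer** (N neurons). Each first-layer neuron connects
   one-to-one to its partner with a fixed +25 weight (`W_FS`, diagonal,
   never updated); each second-layer neuron feeds back onto every *other*
   first-layer neuron with an initially −50 inhibitory weight (`W_SF`,
   zero diagonal) — lateral inhibition, producing winner-take-all
   competition.

After every training presentation the **inhibition-update / synaptic
wiring rule** runs on the first-layer spike counts S: the most active
neuron m (if S_m ≥ 4) is treated as trained for that input and its row of
`W_SF` is updated for every other neuron k that fired at least once and is
still inhibited (entry < 0):

    W_SF[m,k] += L1·(S_k − S_k_prev)   if the count increased   (L1 = 0.5)
    W_SF[m,k] += L2·(S_k − S_k_prev)   otherwise                (L2 = 0.07)

where S_prev are the counts of the immediately preceding presentation.
Any entry that rises above the wiring threshold −38 while still negative
is converted to a fixed +25 excitatory weight: neuron k is *wired* into
m's assembly and subsequently co-fires with it. Wired entries are frozen
permanently; the rule never unwires.

**Decoding** is Bayesian over population spike counts. Training counts are
re-modeled per (class i, neuron j) as Poisson with rate λ_ij (class mean,
floored at 1e-3), with a responsiveness prior P(c_i|n_j) (Laplace-smoothed
fraction of class-i presentations in which neuron j fired, normalized over
classes per neuron). At test time each neuron's class score
prior × likelihood is normalized over classes in log space, the per-neuron
posteriors are combined with weights s_j/Σs (see below), and the argmax
class is reported. A Gaussian count model (per-cell mean/SD, SD floored at
0.5) is provided for comparison; on the sparse low counts this network
produces, the Poisson family decodes better.

## Synaptic efficacy convention

The Euler form above scales input current by dt/τ_m, so with R = 1 a
single spike through a +25 synapse would depolarize its target by only
1.25 mV and the ±25/−50 inter-layer weights would be dynamically inert:
the one-to-one relay could never fire and neither lateral inhibition nor
the wiring rule would ever engage. Reference simulators in this network
family instead inject synaptic input directly into the membrane voltage.
We therefore default the network-level membrane resistance to R = τ_m/dt
(= 20), under which one weight-w spike moves the membrane by exactly
w mV: a +25 relay spike lifts a resting neuron precisely to threshold,
and a −50 inhibitory spike suppresses a competitor decisively. The
integrator itself is unchanged (and is verified against the closed-form
exponential solution with R = 1); the choice only fixes the unit of
synaptic weight, and both R values are configurable per layer.

## STDP amplitudes

The pairwise rule potentiates by A⁺·exp(−Δt/τ⁺) when the presynaptic
spike precedes (or coincides with) the postsynaptic spike, and depresses
by A⁻·exp(−|Δt|/τ⁻) otherwise, τ± = 1 ms, weights clipped to [0, 1]. (A
printed variant of the depression branch in the source literature has the
exponent growing with delay; we implement the standard decaying form.)
The online realization keeps one exponentially decaying eligibility trace
per pre and post neuron (all-to-all pairing); for isolated spike pairs it
reproduces the pairwise rule to machine precision, which the tests assert
delay by delay.

Two amplitude conventions circulate for this architecture family. The
nominal values (A⁺, A⁻) = (1e-4, 1e-2) describe the *rule class*
`stdp_pair_update` and `STDPParameters` default to them. The reference
simulator those values are drawn from, however, applies its amplitude
pair as (pre-spike depression, post-spike potentiation) = (1e-4, 1e-2) —
i.e. potentiation 1e-2 and depression 1e-4. The distinction is not
cosmetic: with potentiation at 1e-4 and depression at 1e-2, every
post-spike's worth of potentiation on an active synapse is outweighed
roughly 100-fold by the depression from the surrounding presynaptic
spikes, the rule is net anti-Hebbian, no class template can form, and the
decoder stays at chance. The network configuration therefore defaults to
the functional assignment (potentiation 1e-2, depression 1e-4), which
produces stable class assemblies within a few hundred presentations. Both
amplitudes are configurable.

Each first-layer neuron's incoming weight column is rescaled to a fixed
total once per presentation (competitive normalization). The total
matters: with τ_m = 20 ms and a 25 mV gap between rest and threshold, a
sparse stroke image (~100 bright pixels at ≤ 0.1275 spikes/ms) must
sustain more than 25/20 ≈ 1.25 mV/ms of average drive for the layer to
fire at all. The conventional total of 78.4 used by networks with a
−52 mV threshold and ~100 ms membrane constant delivers only ~0.9 mV/ms
here — a silent network. The default is 160, which yields winner firing
rates of 10–20 spikes per 350 ms presentation, the regime in which the
S_min = 4 wiring condition and the count-based decoder are meaningful.

## Decoder neuron weighting

Combining the per-neuron class posteriors requires a weight for each
neuron — formally the attribution term P(n_j|s). Giving every neuron an
equal vote fails in practice: in a 100-neuron network a typical
presentation activates ~10 neurons, and the ~90 per-neuron posteriors
computed from near-zero counts simply echo the responsiveness prior.
Because the prior is globally tilted toward whichever class drives the
network hardest, those uninformative votes dominate the sum and the
decoder returns the same class for every input. We estimate P(n_j|s) by
neuron j's share of the observed spike total, s_j/Σ_k s_k (uniform when
no spikes at all), so that only neurons that actually responded carry
votes, in proportion to the evidence they contributed. With this
weighting the decoder reaches the Bayes-optimal accuracy on synthetic
count data (tested) and near-perfect accuracy on the end-to-end synthetic
task. This estimator is our design choice for an ambiguous term, not a
claim about any other implementation.

## Synthetic data

The generator emulates the statistics this architecture assumes of
handwritten-character data: a stable spatial prototype per class, sparse
bright strokes (intensity 230) on a dark background, intensities in
[0, 255]. Ten geometric prototypes are defined (bars, diagonals, cross,
X, square outline, disc, ring, T); a sample is its prototype shifted by a
uniform integer offset in ±2 px on both axes plus additive Gaussian pixel
noise (SD 20, clipped to [0, 255]). Classes are balanced and generation
is fully seeded. What it does *not* emulate: within-class shape variation
(slant, stroke width, topology changes), correlated noise, or intensity
gradients along strokes — so passing end-to-end tests demonstrates that
the mechanism learns stable sparse patterns under noise and jitter, not
that it reaches any particular accuracy on real handwriting.

## Numerical and procedural choices

- **Synaptic delay**: both inter-layer paths (relay and inhibition) act
  with a one-timestep delay; within a step, layers are updated
  first-then-second from the previous step's spikes, which removes any
  within-step ordering ambiguity.
- **Threshold test** is inclusive (u ≥ θ), evaluated after the
  integration sub-step; spiking neurons reset to rest and are clamped
  there for the refractory period.
- **Rest interval** (150 ms, configurable): with zero input the membrane
  decays monotonically toward rest and cannot cross threshold, so the
  interval is applied in closed form — membranes reset to rest,
  refractory clocks expire, adaptive-threshold offsets decay by
  exp(−rest/τ_θ). This is exact for spike output and costs no simulation
  time.
- **Between presentations** membranes restart from rest; adaptive
  threshold offsets persist (homeostasis needs memory across inputs).
- **Evaluation and the post-training counting pass** are fully frozen: no
  STDP, no normalization, no wiring, and no adaptive-threshold change.
- **Tie-breaks**: the maximum-spiking neuron and the predicted class both
  resolve ties toward the lowest index.
- **Degenerate inputs**: an all-dark image yields an empty raster and
  zero spikes throughout; a presentation in which no neuron reaches
  S_min = 4 skips the wiring rule entirely (prev-counts still roll
  forward); neurons silent for an entire training class receive the λ
  floor and a uniform prior, so they can never veto a class.
- **Numerical hygiene**: all likelihoods are computed with log-PMFs and
  normalized via log-sum-exp; λ ≥ 1e-3 and Gaussian SD ≥ 0.5 floors
  prevent zero-likelihood lockout; weight updates are clipped to
  [w_min, w_max] after every step.
- **Randomness**: a single master generator is fanned out (spawned) into
  independent child streams per phase — weight initialization, training
  encodings, counting pass, evaluation — so each phase reproduces
  independently and identical seeds give bit-identical runs.

## Problem sizes

The shipped experiment configuration trains 100 first/second-layer
neurons on 300 presentations of 3 synthetic classes and evaluates on 60
held-out samples over 10 seeded repetitions; it completes in about a
minute on one CPU and typically ends with ~25 wiring events and > 95%
test accuracy. Full-size replication protocols (1600 neurons, 75,000
MNIST presentations / 102,000 EMNIST presentations, 10 test repetitions)
are documented in `configs/`; they require the IDX files on disk and
hours of single-core simulation, and are not exercised by the test suite.

## Known limitations

- Current-based synapses and a single homogeneous LIF parameter set per
  layer; no conductances, no Hodgkin–Huxley or Izhikevich dynamics.
- The wiring rule is permanent — no unwiring or renormalization of wired
  assemblies — so very long runs on drifting data would accumulate stale
  assemblies.
- The decoder treats neurons as conditionally independent given the
  class; correlations induced by lateral inhibition and co-firing
  assemblies are not modeled (they are precisely what the spike-share
  weighting exploits, but the likelihood ignores them).
- Bernoulli-per-timestep encoding slightly underdisperses relative to a
  true Poisson process (variance/mean = 1 − p); at p ≤ 0.1275 this is
  negligible for decoding but visible in dispersion statistics.
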