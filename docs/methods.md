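# Methods

## The model in one paragraph

A two-layer spiking network learns image classes without labels: pixels
drive Poisson spike trains into plastic synapses onto an excitatory
layer, lateral inhibition makes the excitatory neurons compete, and an
adaptive threshold keeps any one neuron from monopolising the response.
Synapses change by spike-timing-dependent plasticity (STDP).  Treating
the vector of synaptic weights over training time as a stochastic
process — an Ornstein–Uhlenbeck process driven by possibly heavy-tailed
(α-stable) noise — the roughness of its sample path carries information
about generalization: heavier-tailed weight dynamics correspond to a
lower Blumenthal–Getoor (BG) index, and empirically to a smaller gap
between training and test accuracy.  Because the BG index is computed
from the training trajectory alone, it can serve as a test-set-free
objective for hyperparameter optimization, which this package performs
with a Gaussian-process surrogate and expected improvement.

## Neuron and network model

Conductance-based leaky integrate-and-fire dynamics per neuron:

    tau dX/dt = (E_rest − X) + g_e (E_exc − X) + g_i (E_inh − X),
    tau_g dg/dt = −g,       g_e/g_i jump by the synaptic weight on a spike.

A neuron fires when `X >= v_thresh + theta`, resets to `v_reset`, and is
refractory for `t_refrac`.  The homeostatic offset `theta` grows by
`theta_inc` per spike and decays with `tau_theta`.

Default constants (all configurable) follow the reference two-layer
implementation this architecture comes from: excitatory `tau` 100 ms,
`E_rest` −65 mV, `E_exc` 0 mV, `E_inh` −100 mV, `v_thresh` −52 mV,
`v_reset` −65 mV, refractory 5 ms; inhibitory `tau` 10 ms, `E_rest`
−60 mV, `E_inh` −85 mV, `v_thresh` −40 mV, `v_reset` −45 mV, refractory
2 ms; `tau_ge` 1 ms, `tau_gi` 2 ms; fixed weights `w_ei` 10.4 (one-to-one
excitatory→inhibitory) and `w_ie` 17.0 (inhibitory→all-but-partner).

Integration is clock-driven explicit Euler at `dt` = 0.5 ms for the
membrane; conductance, threshold and trace decays use exact exponential
factors, so the only O(dt) error is in the membrane term (verified by a
first-order-convergence test against the closed-form passive decay).
Recurrent spikes are delivered at the next clock step; the membrane is
clamped to `v_reset` during refractoriness while conductances continue
to evolve.  A fused numba kernel and a pure-numpy reference path
implement identical per-step semantics (a test asserts bit-identical
results); the kernel makes one 350 ms presentation cost a few
milliseconds at the desk scale.

Input images are rate-coded: a pixel of intensity I fires at
I/4 Hz (255 → 63.75 Hz) as an independent Bernoulli-thinned Poisson
train for 350 ms.  If a presentation elicits fewer than 5 excitatory
spikes, the rate ceiling is raised by 32 Hz and the image re-presented
(up to 20 boosts).  Between presentations the network rests silent for
150 ms; because nothing arrives during the rest, the relaxation is
applied in closed form rather than stepped (exact for conductances,
threshold and traces; the membrane closed form ignores the residual
conductance drive inside the first few ms of silence, which is
negligible at these time constants).

## STDP rules

A pairing with pre-minus-post lag u changes the weight by
`eta (1 + zeta) H(W; u)`, `zeta ~ N(0, sigma^2)` drawn independently per
synapse per event (untruncated by default; a draw below −1 flips the
update sign with negligible probability at the default sigma, and a
truncation switch exists).  The window H applies the scaling functions
with `exp(−|u|/tau±)` kernels; an exact tie u = 0 counts as potentiation
(ties are artifacts of the discrete clock).  Scaling functions:

* add:   a+ = c+, a− = c−  (hard bounds [0, w_max] enforced by clipping)
* mult:  a+ = c+, a− = c− W
* log:   a+ = c+ exp(−W/(W0 γ));  a− = c− W/W0 below W0, and
         c− [1 + ln(1 + S(W/W0 − 1))/S] above it.

The log rule interpolates between the others: S→0, γ→∞ recovers the
mult rule (tested to 1e-6 relative); S→∞ flattens depression toward the
add rule (tested as monotone slope decrease in S).  The default log
calibration sets `c− = (τ+/τ−) c+ e^{−1/γ}` so that
`τ+ a+(W0) = τ− a−(W0)` — the stated fixed-point balance — making W0 a
genuine equilibrium of the pair rule.

Online implementation uses additive traces (all-to-all pairing): a pre
spike bumps `x_pre` by `A_pre0` and depresses by `eta a−(W) x_post`; a
post spike bumps `x_post` by `A_post0` and potentiates by
`eta a+(W) x_pre`.  For an isolated pair this reproduces the pair rule
exactly (tested symbolically).  Because `A_post0` multiplies every
depression event, it rescales the effective LTD amplitude: the desk
network presets use `A_post0` = 1 for the add rule (so `c+τ+ < c−τ−`
indeed yields the depression-dominant drift that gives add-STDP its
bimodal weight distribution) and for the mult rule (placing its
equilibrium `c+τ+/(c−τ−)` at 0.25 of the weight bound), but keep
`A_post0` = 0.5 for the log rule together with a c− chosen from the
*trace-level* balance `a+(W0) A_pre0 τ+ = a−(W0) A_post0 τ−`
(c− ≈ 0.98 at the defaults).  The preset's LTP/LTD amplitude ratio
(SFR = c+/c−) then sits near 1 — the rule's canonical near-unity
calibration — the trained weight distribution forms its signature long
right tail above W0 instead of piling at the bound, and the 0.9–2.1 SFR
sweep spans a gradual-decay regime below 1 and a memorization regime
above it instead of collapsing the network.

Learning-rate scales: the rule-level defaults carry the benchmark value
`eta` = 2e-4; the network presets use the 0.05–0.2 scale at which the
sweep experiments and the optimizer domain are defined.  The two scales
appear in different sources and are kept as plain config values rather
than reconciled.

## Heavy-tail analysis

Symmetric α-stable deviates come from the Chambers–Mallows–Stuck
construction (cross-checked against an independent implementation by a
KS test; α = 2 reduces to a Gaussian with variance 2·scale², α = 1 to a
Cauchy).  Lévy-driven OU trajectories use Euler–Maruyama with the
dt^{1/α} noise scaling.  A single-synapse membrane SDE — exponential
leak, Poisson input jumps of size W, state-dependent Poisson output
resets — is simulated with exact leak between jump windows; with no
output spiking its stationary mean is the shot-noise value W·λ·τ,
which the simulator reproduces within Monte-Carlo tolerance.

The tail index α of a sample is estimated by the block log-moment
ratio: center the values, sum them in K blocks of size m
(default ⌊√N⌋), and set

    1/α̂ = (1/log m) [ mean_j log|Y_j| − mean_i log|X_i| ],

exact in expectation for stable laws since block sums scale like
m^{1/α}.  Estimates are clipped into (0, 2]; exact zeros are floored at
machine-tiny before the log.  Recovery on synthetic stable data:
mean absolute error ≤ 0.1 for α ∈ {1.1, 1.4, 1.7, 2.0} at N = 1e5.

The BG index of a training run is the maximum per-layer α̂ of the
final-iteration weight-increment vector (one plastic layer here, so the
max is over a single group; the per-layer structure is kept for
forward compatibility).  Two desk-scale choices matter:

* iteration granularity — per-synapse increments must aggregate enough
  plasticity events for rule-specific weight dependence to dominate
  event-count noise; iterations of 600 images (the granularity the
  training-loss protocol also uses) achieve this, 60-image iterations
  do not;
* pooling — with only 100 excitatory neurons the single-iteration α̂
  fluctuates by about ±0.1 between consecutive iterations, the same
  order as the between-rule differences, so the desk experiments pool
  the increments of the final three iterations into one estimate
  (`bg_index(..., last_k=3)`).  Full-scale runs can use the plain
  final-iteration estimate.

Gaussian KDE is implemented directly from its definition with the
bandwidth as the kernel variance t (Silverman's rule by default; the
estimate is known to be bandwidth-sensitive, so t is always explicit in
the API).

## Synthetic data

The generator emulates the statistics the pipeline needs from digit
data at desk scale: 12×12 8-bit images, three or more classes, each
class a prototype of random bright strokes, Gaussian-blurred (σ = 1 px)
into graded intensities.  Per sample, a quarter of the stroke pixels
are occluded and intensities jittered (SD 40 on strokes, 10 on
background), then the presentation order is shuffled across classes.
Prototype pairs are resampled until correlation < 0.5; a
nearest-prototype classifier scores > 90% on the default settings, so
the task is learnable.  The blur is load-bearing: with sharp disjoint
strokes, class-specific pixel support makes per-synapse event counts so
heterogeneous that every STDP rule produces equally heavy-tailed
increments, which real digit data (with overlapping pixel activity)
does not show.  What the generator does NOT emulate: writer-specific
style variation, within-class shape deformation, intensity gradients of
pen pressure, and the 10-class scale of the full datasets — so passing
trend tests here demonstrates mechanism, not full-dataset performance.

## Training, evaluation, desk protocol

Desk study conditions (fixed once): 100 excitatory neurons, 144 inputs,
600-image synthetic set (or larger for the one-epoch sweep), 75/25
stratified train/test split, training stream of 2400 presentations in
iterations of 600, `theta_inc` 0.5–1.0 mV with `tau_theta` 1e4 ms
(homeostasis must act within a short run; the full-scale values
0.05 mV / 1e5 ms act too slowly at this scale and leave most neurons
silent, which both ruins the classifier and freezes most synapses).
Weights are snapshotted at every iteration boundary.

Evaluation freezes learning (η = 0) and thresholds (θ pinned), assigns
each neuron the class with its highest mean spike response (ties to the
lowest class index; all-silent neurons are excluded as unresponsive),
and predicts by the class whose assigned neurons fire most on average.
The training loss max-normalizes per-class mean counts, renormalizes to
a probability vector with 1e-9 smoothing (max-division alone is not a
distribution), and takes cross-entropy against the true label; repeat
evaluations with shuffled order give the spread.  The generalization
error is |train − test| accuracy in percentage points; intermediate
loss evaluations use the held-out subset by default.

The SFR sweep runs in the one-epoch regime (as many unique images as
presentations): when a small image pool is recycled for several epochs,
networks at depression-dominant settings memorize sample-specific
stroke-dropout patterns and the train-test gap inverts the expected
pattern; with unique images the ratio 0.9 is the best-generalizing cell,
as it should be.  The sweep's generalization-error trend across
{0.9, 1.2, 1.7, 2.1} remains statistically flat at this scale — the
effect is of order one percentage point at full scale, below this
setup's per-cell noise — and the corresponding acceptance test reflects
that honestly (see the test suite).

## Hyperparameter optimization

Search space: η ∈ [0.05, 0.2] (log-scaled), σ ∈ [0.1, 1],
S ∈ ℤ∩[1, 10], γ ∈ ℤ∩[10, 100], W0 ∈ (0, 1], c± ∈ (0, 1]²,
τ+ ∈ [10, 20] ms, τ− ∈ [20, 40] ms.  Nominally half-open domains are
clamped at 0.01 so every sampled configuration is valid.  Integer
dimensions round at evaluation time, and candidates are snapped before
surrogate scoring so the model scores what will actually run.

Objective: split the training stream into K folds (K = 2 at desk
scale, trading fold count for per-fold stream length on one CPU), train
one network per fold, return the mean BG index; divergent or
unresponsive folds score the penalty 2.0 (the BG upper bound), keeping
failures maximally unattractive without leaving the objective's scale.
The optimizer never sees test data.  Each evaluation also logs per-fold
training accuracy so the generalizability-trainability tradeoff can be
plotted from the run record.

Surrogate: GP with constant × Matérn-5/2 kernel on the unit cube,
observation jitter 1e-6, y-normalization; at most three penalty values
enter the fit so a run of failures cannot flatten the model.
Acquisition: expected improvement against the best observed value,
maximized by 512 uniform candidates plus 128 Gaussian perturbations of
the incumbent; a flat or degenerate posterior falls back to a flagged
uniform draw.  Initialization: Latin hypercube of 5 points; budget 15
evaluations at desk scale.

## Known limitations

* Desk-scale trends are trends: absolute BG values, accuracies and
  errors here are not comparable to full-scale digit benchmarks.
* The estimator receives a mixture over synapses, not an iid stable
  sample; its value is a summary statistic whose between-condition
  ordering, not absolute calibration, carries the signal.
* Frozen synapses (exact-zero increments) bias α̂ via the centering
  atom; the desk conditions keep the frozen fraction low but it is not
  zero.
* The Hausdorff dimension itself is never computed from covers; the BG
  index is used as its operative bound throughout.
* Event-driven simulation, axonal delays beyond one clock step,
  triplet/voltage/stochastic STDP variants and supervised readouts are
  out of scope.
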