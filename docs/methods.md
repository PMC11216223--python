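# Methods

## The model

A disk-shaped cell of radius `R` swims in a plane at constant speed `v`
through a static, radially symmetric chemoattractant field centred on the
origin.  Its heading `theta(t)` is the only controlled degree of freedom:

    d theta = a_t dt + sqrt(2 D_R) dW,

where `a_t` (rad/s) is the steering action produced by a navigation policy
and `D_R` is a rotational diffusion coefficient.  The stochastic equation is
integrated by Euler–Maruyama: each step updates the heading first (action,
then the Gaussian increment `sqrt(2 D_R dt) z`), and the cell then
translates `v dt` along the *new* heading.  The alternative order differs
at O(dt) and is irrelevant at the step sizes used.  Positive actions turn
the cell counterclockwise (left).

### Concentration fields

The default profile is exponential, `C(r) = C0 exp(-lambda r)`, with
`lambda = sqrt(kappa / D)` the inverse length scale of a diffusion–decay
balance.  The defaults `D = 100 um^2/s` and `kappa = 0.1/s` give
`lambda = 0.032 /um`.  Two alternatives are provided: an algebraic profile
`C0 / (1 + lambda r)^2` and the true steady state of the 2D
diffusion–decay equation with a point source, `A K0(lambda r)` (modified
Bessel function of the second kind).  Because `K0` diverges at the origin
there is no natural "peak value" to pin `A` to; we scale the Bessel profile
to agree with the exponential profile at a configurable `match_radius`
(default 1 um), which makes the profiles comparable at the cell scale.  In
the far field the Bessel profile's log-slope tends to `-lambda`, so the two
differ only by a slowly varying prefactor.

### Sensing

`K` sensors (default 5) sit on the cell perimeter at angles
`theta + 2 pi k / K`; sensor 0 faces the direction of motion and the frame
co-rotates with the body, which is what gives "left" and "right" sensors a
stable meaning in the attribution analyses.  Each sensor is a perfect
instrument: at every step it counts the molecules inside its detection disk
of radius `r_s = R sin(pi/K)` (the largest radius at which K disks tile the
perimeter without gaps).  Because the concentration is nearly constant over
a sensor disk, the expected count is `E(M_i) = C(d_i) pi r_s^2` with `d_i`
the distance of the sensor centre to the source; the unit tests check this
approximation against numerical disk integrals (agreement to ~0.2% at the
default geometry).  Counts are independent Poisson draws per sensor and per
step — no receptor binding kinetics, no temporal correlation — and are
compressed by the Weber–Fechner transform `m_i = log(M_i + 1)` before they
reach the policy.

### Episodes and reward

An episode starts at a uniformly random distance `d0` from the source (the
direction and the initial heading are also uniform) and ends when the cell
comes within `delta` of the source or after `t_max`.  Each episode draws
its own peak concentration `C0` log-uniformly from a configured interval,
so one trained policy must cope with a range of signal-to-noise ratios.
The terminal reward is

    R = (t_max - tau)/t_max + max(-1, (delta - d)/(d0 - delta)),

with `d = delta` on arrival and `tau = t_max` on timeout, so exactly one
term is active: arrivals are scored by speed (in (0, 1]), timeouts by how
much ground was gained (in [-1, 0]).  No intermediate rewards are given.

Default geometry: `d0` in [100, 500] um, `delta = 10` um, `t_max = 2000` s,
`dt = 0.1` s, `v = 5` um/s, `D_R = 0.025`/s, `C0` in [16, 160] /um^2.
With these values a straight run takes at most ~100 s, a small fraction of
the horizon, while a blind swimmer almost never arrives — its efficiency
(see below) computes to ~0.02.

## Policies

Three neural variants share one architecture family: inputs -> (optional
GRU) -> tanh MLP -> three heads.  The *spatial* variant is a stateless
feedforward map from the K instantaneous measurements.  The *temporal*
variant sees only the sensor average `<m>` plus its own previous action,
passed through a gated recurrent unit whose hidden state is the cell's
"biochemical memory".  The *combined* variant feeds all K measurements and
the previous action through the GRU and can therefore express anything
between a purely spatial and a purely temporal strategy.  The heads emit
the action mean `mu` (squashed by `action_scale * tanh`, default scale
pi rad/s — bounding the mean stabilises policy optimization), a
state-dependent standard deviation `sigma = softplus(.)` initialised near
half the action scale, and a value estimate `V` used only during training.
Actions are sampled from `Normal(mu, sigma)` during training and equal `mu`
at evaluation (by the end of training `sigma` has collapsed toward zero).

Measurements are affinely rescaled, `(m - 4)/3`, before entering the
network: over the studied concentration range `m` spans roughly 0–9, and
without centering the tanh/sigmoid units start saturated and learning
stalls.  The previous action is fed back scaled by `1/action_scale`.

Hand-coded baselines implement the same interface: a *blind* agent (zero
action — pure persistent random walk), a *memory-kernel* comparator that
steers by a kernel-weighted history of the left–right sensor contrast
`sum_i sin(2 pi i/K) m_i(t - l)` (a delta kernel reduces it to an
instantaneous comparator), a *switching* strategy that runs a temporal
policy until the mean measurement first crosses a threshold and then
latches irreversibly onto a spatial policy, and a perfect-aim *oracle*
(test-only; it reads the true cell state).

## Training

Policies are trained by proximal policy optimization over batches of
independent vectorized episodes with the purely terminal reward.
Advantages use generalized advantage estimation with terminal bootstrap
zero and are normalized per update; the loss is the clipped surrogate
(epsilon = 0.2) plus a value regression term (coefficient 0.5) minus an
entropy bonus (1e-3), optimized by Adam with a linearly decaying step.
Feedforward variants shuffle flattened transitions into minibatches;
recurrent variants replay whole episodes in order from the zero initial
hidden state (episodes are short at the scales used, so no truncated
backpropagation-through-time is needed) and minibatch over episodes.

Because episodes carry a single terminal reward, we train undiscounted
(`gamma = 1`) with `lambda_GAE = 0.95`; `gamma < 1` is supported but only
shortens the effective credit-assignment horizon here.  The recurrent
networks, PPO, and the attribution gradients all run on a small in-package
reverse-mode automatic differentiation engine over numpy arrays
(`chemonav.autodiff`); a finite-difference test battery pins its
correctness.

### Scaled-down study conditions

The full-scale experiments behind the original phenomenology require on the
order of millions of simulated episodes.  The package's reference training
configuration (used by the test suite) is a scaled-down counterpart chosen
to finish on a single CPU core in minutes: start distances `d0` in
[40, 70] um, `t_max = 30` s, `dt = 0.2` s, a fixed nutrient-rich
concentration `C0 = 1600 /um^2` (100x the noisy-regime floor), cell radius
`R = 2` um, networks with hidden size 32 and one 32-unit MLP layer, and a
budget of 256 episodes x 200 updates per variant.  Optimizer settings are
tuned per architecture class under that matched data budget (learning rate
1e-3 with transition minibatches of 4096 for the feedforward variant; 2e-3
with episode minibatches of 64 for the recurrent ones — recurrent learners
need more, smaller gradient steps per batch to keep pace).  Under these
conditions all three variants learn: the spatial and combined policies
reach efficiency ~0.75 (about 6x the blind baseline at the same geometry)
and the temporal policy ~0.67, with exploration noise decaying several-fold
in every case.  Passing these scaled checks demonstrates that the training
loop optimizes what it should, not that it reproduces full-scale
efficiency-versus-size curves.

## Evaluation

The chemotactic efficiency of a run is
`eta = (d0 - delta)/(v tau)` — the straight-line travel time over the
realized arrival time — and a strategy's efficiency is the mean over
independent deterministic-mode episodes.  `eta <= 1` holds exactly (a path
cannot close radial distance faster than its own length).  Evaluation uses
a horizon of 4x the training `t_max`; episodes that still fail enter the
mean with `tau` equal to that horizon (conservative), and the failure
fraction is always reported alongside.  A flag restricts the average to
arrivals instead.  Standard errors come from a bootstrap over runs.

## Attribution

Input importances use integrated gradients with zero baseline: a midpoint
Riemann sum (default 512 points) of the action-mean gradient along the
straight path from `x' = 0` to the input.  The attribution target is the
deterministic steering output `mu`; the sigma and value heads are not
attributed.  Completeness — attributions summing to `pi(x) - pi(0)` — is
reported with every record and warned about above a 1e-3 relative
tolerance at fine grids (coarse grids, used where only attribution ratios
matter, relax the warning threshold).

The memory-usage statistic is
`U_h = sum_{i in hidden} |I_i| / (sum_hidden |I_i| + sum_measurements |I_i|)`,
with previous-action attributions excluded from both sums; it is invariant
to rescaling all attributions and undefined (returned as NaN) when both
sums vanish.  Spatial policies have no hidden inputs and score exactly 0.

Through-time attributions unroll the recurrence over a trailing window of
`T_back` observations (default 300 steps), holding the window's initial
hidden state and the recorded fed-back actions fixed, and attribute the
current action jointly to all `T_back x K` past measurements.  For a
spatial policy every positive lag receives exactly zero; for a temporal
policy the per-unit-input attribution is identical across sensors at every
lag, because only the sensor mean enters the network.

## Numerical and reproducibility choices

* Every episode owns a dedicated counter-based random stream spawned from
  one root seed, consumed in a fixed order; results are therefore
  independent of how episodes are grouped into batches, and the batch
  runner's sensor counts are drawn by inverting the Poisson CDF (via the
  regularized incomplete gamma function) at pre-drawn uniforms, which
  vectorises across episodes with state-dependent means.
* Policy inference matmuls go through `einsum`, whose per-element reduction
  order is independent of the batch size; BLAS products are reserved for
  the training path, where bit-stability across batch shapes is not
  required.
* Checkpoints are deterministic JSON documents (base64-encoded raw array
  bytes plus metadata); save -> load -> save is byte-identical, and a
  version field is checked on load.
* Degenerate inputs: a zero-width concentration interval pins `C0`;
  `sigma = 0` makes action sampling deterministic; all-failure evaluation
  returns NaN summaries with explicit failure counts.

## Limitations

The synthetic world omits receptor kinetics, three-dimensional motion,
fluid mechanics, moving or fluctuating sources, and inter-cell
interactions; sensor counts are temporally uncorrelated by construction.
Conclusions from the scaled-down training conditions are directional only:
they exercise the machinery at small problem sizes and do not reproduce
full-scale efficiency-versus-size curves, and the temporal variant in
particular is budget-limited rather than physics-limited at desk scale.
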