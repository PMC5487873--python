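# Methods

## Model

Each unit follows the continuous-time firing-rate equation
`tau dx/dt = -x + W tanh(x) + w S(t)`, `r = tanh(x)`. The recurrent matrix
`W` lives on a directed Erdős–Rényi graph: every off-diagonal entry is
present independently with probability `p` (default 0.1) and, when present,
drawn from `N(0, g^2/(pN))`; the diagonal is zero (no self-connections).
Whether the underlying graph should be directed is genuinely open — the
construction is stated only as an Erdős–Rényi graph — and we choose the
directed reading because `W` enters the dynamics asymmetrically. Input
weights are standard normal. The gain `g` sets the spectral radius of `W`
(≈ `g`), separating a globally contracting regime (`g < 1`) from one with
multiple equilibria and saddle points (`g > 1`).

The drive protocol fixes the sinusoid's angular frequency at `alpha = 10`
and varies the neuron time constant `tau = rho / alpha` instead, so the
sinusoid has the same per-step resolution (~62.8 steps per period at
`dt = 0.01`) for every timescale ratio `rho = 2*pi*tau/tau_F`. Integration
is forward Euler with `dt = 0.01` for 3500 steps: silence for 200 steps, a
pulse of amplitude 5 for 50 steps (to collapse the state into a bounded
region), then the unit sinusoid, whose phase origin we place at the first
post-pulse step (the protocol fixes the ordering but not the phase; the
choice is recorded in run metadata). The first 1500 steps are discarded as
transient. Initial states are `N(0, 0.5^2)` — the initialisation
distribution is unstated in the source protocol, and this scale matters
more than one would like (see "Windows dominated by transients" below).
Simulating the time-rescaled equation `dx/dt' = -x + W tanh(x) +
w sin(rho t')` with step `dt/tau` is algebraically identical to the
real-time path; the equivalence is exercised in the test suite rather than
duplicated in the library.

## Stationary-point machinery

For frozen input `s`, roots of the tau-free residual
`-x + W tanh(x) + w s` are found with MINPACK's modified Powell hybrid
method (a dogleg-type trust region) using the analytic Jacobian
`W ∘ B - I`, `B_ij = 1 - tanh^2(x_j)`, followed by Newton polishing.
A solve only counts as converged when every residual component is below
the stationarity tolerance, default `1e-13`: the ideal criterion of
`1e-15` sits at the rounding floor of an N-dimensional residual and is not
reliably attainable, so the tolerance is explicit, configurable and always
reported. Failures return the best candidate and its residual rather than
a near-miss dressed as success.

Continuation walks `s` from the exact trivial root at `s = 0` outward in
steps of `Delta = 0.01` to `±1`, warm-starting each solve; a branch aborts
after 5 consecutive failures. By oddness of `tanh`, `phi(-s) = -phi(s)`
exactly; the continuation output satisfies this to ~1e-9, a useful global
health check. The random-restart census draws starting points uniformly
from `[-1, 1]^N` (the tanh saturation scale; the restart distribution is
another unstated detail) and merges converged points closer than `1e-4`.

Classification uses the signs of the eigenvalue real parts of the tau-free
Jacobian — the `1/tau` prefactor is a positive scalar and cannot change
them. Exact zeros are flagged marginal rather than silently binned. Two
eigenvalue orderings are exposed because both are scientifically relevant:
largest real part (decay/growth rates, used for classification) and
largest modulus (used to pick the rotation plane). The rotation plane is
the orthonormalised span of the real and imaginary parts of the chosen
complex eigenvector — the 2×2 rotation block of the real Jordan form. Note
that for stable networks of this ensemble the largest-modulus eigenvalue
is complex for only roughly half of (network, s) draws; the robust
statement is that complex pairs with negative real parts exist at every
sink, not that they always lead the spectrum.

## Dimensionality estimators

`D_PCA` is the smallest number of principal components of the
post-transient rate matrix whose cumulative explained variance reaches the
threshold (default 0.95), averaged over runs.

`D_kNN` cross-predicts between two runs: delay-embed neuron j's activation
in run A (dimension `m`, lag `tau_d = 4`), and for each usable time t find
the `k = 4` nearest embedding vectors, excluding a Theiler window of
±`tau_d` steps around t to rule out trivially adjacent-in-time matches
(standard practice for embedded time series, though unstated in the
protocol we follow). The prediction of neuron j in run B at `t + h` is the
mean of run B at the neighbours' `+h` successor times; the score is
`max(0, 1 - MSE/Var)`, invariant to affine rescaling of the target.
`D_kNN` for the (neuron, ordered run pair) sample is the smallest `m`
whose score reaches the threshold, capped at `max_dim = 20` and flagged
saturated; the estimate aggregates 10 sampled neurons × 5 sampled ordered
run pairs (mean, rounded half-up, standard error attached).

Two defaults deserve justification:

* **Horizon `h = tau_d`, not one step.** At ~63 samples per drive period,
  a one-step-ahead target is recoverable from local smoothness alone: any
  smooth signal scores ≥ 0.95 at embedding dimension 1, so the estimator
  would return 1 everywhere and fail even the clean-sinusoid ground truth
  (a sinusoid needs two embedding coordinates). Predicting one full
  embedding lag ahead makes the score sensitive to the attractor's
  geometry. The horizon is a config field for users who want the literal
  one-step variant.
* **Run pairing.** Runs within an estimate share the reservoir and input
  weights and differ in their random initial state; the rho sweep redraws
  the whole network per (rho, replicate) point. Sharing weights is what
  makes cross-prediction measure the structure the drive imposes on *this*
  network's flow; the all-fresh-weights pairing (`redraw="network"`) is
  available and probes only drive-locked structure.

For long series the score is evaluated on an evenly spaced subsample of at
most 750 query times (the neighbour library is never subsampled); this is
a pure runtime measure with no measurable effect on the estimates at the
series lengths used here.

## Windows dominated by transients — what results do and do not show

The analysed window is fixed at 35 time units (3500 steps × dt = 0.01)
while the slowest relaxation time of a stable network is about
`tau/(1-g) = rho/((1-g)*10)` time units. For `rho ≳ 50` at `g = 0.9` the
window is therefore *transient-dominated*: two runs started from different
states provably do not converge toward a shared orbit inside the window
(at `rho = 3000` the run-to-run distance decays from 0.70 to only 0.63
while the driven signal's scale is ~0.008; at `g = 1.5` the distance
grows). In that regime the cross-run estimator measures initialisation
overlap as much as attractor geometry, and its output is sensitive to the
unstated initial-state scale. Consequences, verified empirically:

* Low `rho` (≲ 20, stable): transients die inside the discard window, runs
  collapse onto the same driven loop, and `D_kNN = 2` is robust — this is
  the regime where the estimator means what it says.
* Intermediate `rho` (stable 50–500): many (neuron, pair) samples saturate
  at the cap; per-rho means are large and high-variance. The sweep still
  shows the qualitative signature — a plateau at 2, a single broad peak,
  and a decline at high `rho` — but peak height and location depend on the
  initialisation convention, and we do not read quantitative meaning into
  them.
* Very high `rho` (≥ 1e4): the network is effectively frozen; per-neuron
  activity is a slow near-monotone drift that one embedding coordinate
  predicts, and estimates fall back toward 1–1.5.

The same caveat applies to the unstable `N = 800, g = 1.5` band: sampled
trajectories there are smooth and strongly three-dimensional in the linear
sense (first three PCs ≈ 99.9% of variance, comfortably above the 75%
headline bound), but cross-run `D_kNN` saturates rather than settling at
3 because unsynchronised runs share too little. Published point values for
`D_kNN` in transient-dominated regimes should therefore be compared
qualitatively, not digit-by-digit, against this implementation; the
acceptance script reports our honestly computed numbers either way.

## Synthetic validation fixtures

`make_fixture` generates signals whose attractor dimensionality is known:
exponential relaxation (1), a sinusoid (2), a two-incommensurate-frequency
torus curve (3), rank-r linear-subspace clouds (`D_PCA = r`), and white
noise (unpredictable; the kNN estimator must saturate its cap). Periodic
fixtures carry a 2% observation-noise floor: a noiseless periodic signal
sampled on a commensurate grid has exact same-phase recurrences, which
give zero-distance neighbours and a perfect one-dimensional forecast —
the fixture would test grid arithmetic, not geometry. The torus uses
periods of ~24 and ~34 steps so the 4-step lag subtends a substantial
phase angle; with the slow default periods the delay map is nearly
collinear and the estimator needs extra dimensions for no geometric
reason. These fixtures emulate clean attractor geometry only — no
network-like transients, no state-dependent noise — so passing them shows
the estimators are correctly implemented, not that network estimates in
transient-dominated regimes are unbiased.

## Geometry

The reduced frame is the PCA basis of the stationary-point locations only
(a property of the vector field, not of a run), default `m = 2` with
`m = 3` supported. `d_phi` pairs the state at time t with `phi(S(t))` at
the nearest continuation grid value — the time-paired reading of
"distance between the network state and the stationary point trajectory" —
and the nearest-point-on-curve variant is reported alongside as a lower
bound. The smallest enclosing sphere uses Welzl's randomised incremental
algorithm with the support solved by a circumsphere linear system; it is
exact (tested against combinatorial brute force to 1e-9), and the slow
drive → tight tracking intuition holds with the caveat that the tracking
lag scales like `rho × |phi'(s)|`, so skeletons with steep stretches show
sizeable `d_phi` even at modest `rho`.

## Problem sizes

The default test suite runs small networks (N = 40–60) for unit checks
and N = 200/800 only inside the acceptance tests, with 2–3 replicates per
sweep point and 10–12 point rho grids; `scripts/acceptance.py` uses 5
replicates for the fixed-rho stable targets, 3 for the stable sweep, and 2
for the N = 800 sweeps. Sweep tables carry per-point seeds so any cell can
be recomputed bitwise in isolation.

## Known limitations

* Euler integration only, matching the protocol; no adaptive stepping, so
  `dt/tau > 2` is unstable (guarded by an explicit divergence error).
* No pseudo-arclength continuation or branch switching: the continuation
  tracks the branch connected to `phi(0) = 0`; disconnected branches are
  only reachable via the random-restart census.
* The kNN estimator's absolute values in transient-dominated regimes
  depend on initialisation conventions (see above); its low-`rho` and
  fixture behaviour is the validated core.
* Saddle sub-taxonomy in three dimensions (rotational saddles etc.) is not
  automated; eigenvalues and rotation planes are exposed for manual study.
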