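# Methods

## Model

The package models the dominant mode of worm whole-brain population
activity as a controlled, damped double-well oscillator:

    dx = y dt + σ dW₁
    dy = [f(x, β) + γ y + u(t)] dt + σ dW₂,     f(x, β) = −(x+1)(x−β)(x−1)

x tracks the first PCA score v₁ of the derivative traces, y the second.
The cubic places sinks at x = ±1 (forward and sustained-reversal
behavior) and a saddle at x = β; β ∈ (−1, 1) is therefore the relative-
stability dial.  At a fixed point (x*, 0) the Jacobian is
[[0, 1], [f′(x*), γ]], so eigenvalues solve λ² − γλ − f′(x*) = 0, and
f′(±1) = −2(1 ∓ β): at β = 0 both wells are equally stable with slope
−2.  The general machinery (`PolynomialField`) accepts any
conjugate-closed root multiset, so regimes where the saddle and forward
root merge into a complex pair (forward well lost) are representable;
`ModelParams` itself stays real.

Noise enters **both** state equations with independent Wiener processes
and a common amplitude σ — the literal reading of the stochastic model
as written with σ dW on each line.  Whether the two terms share one
process is not determinable from the trajectory statistics we use; two
independent processes is the conventional choice.

## Integration

Euler–Maruyama with exactly one step per recorded frame, of size dt
(itself a fitted parameter that maps frames to model time):

    x_{k+1} = x_k + y_k·dt + σ√dt·ξ₁
    y_{k+1} = y_k + [f(x_k) + γ·y_k + u_k]·dt + σ√dt·ξ₂

This scheme is first-order: at the fitted dt ≈ 0.29 its deterministic
sup-norm error against an adaptive high-accuracy ODE solve over 500
frames is ~2–5×10⁻², dropping below 10⁻² for dt ≲ 0.05–0.1.  The test
suite checks both the small-step accuracy and the first-order shrink of
the error with dt.  The energy V(x, y) = y²/2 − ∫₀ˣ f decreases along
the exact flow when γ < 0 and u = 0 (dV/dt = γy²); the discrete map
respects this only up to the local truncation error, so monotonicity is
asserted with a per-step slack of 0.25·dt² (measured worst-case
increase ≈ 0.115·dt²).  Trajectories whose state leaves |x|, |y| < 10⁴
raise a divergence error carrying the step index; the fitting objective
converts this into a large finite penalty (10⁶) so simplex search can
proceed.

## Preprocessing

1. first differences of each neuron's ΔF/F trace, divided by the frame
   interval (the differencing scheme is a free choice; first differences
   make the synthetic embedding exactly invertible);
2. per-neuron mean centering, PCA over time (scikit-learn);
3. drift correction: subtract a centered moving average from each PC
   score, partial windows at the edges;
4. orientation and scaling: flip v₁ so the forward-state mean exceeds
   the reversal mean, subtract the midpoint of the two cluster means,
   and rescale both modes so the cluster means land exactly at +1 and
   −1; v₂'s sign is set so corr(Δv₁, v₂) ≥ 0, consistent with x′ = y.

Two choices deserve comment.  *Window length*: the drift window
defaults to the full recording (n − 1 frames).  Behavioral dwells are
~150 frames and a cycle ~400; a window of a few hundred frames tracks
genuine state structure and subtracting it both decorrelates v₁ from
the latent x (measured |corr| drops to ~0.87 at a 500-frame window) and
inflates the apparent transition amplitude, which badly biases the
parameter fit.  A recording-length window still removes slow monotone
trends (photobleaching) but leaves state structure intact
(|corr| ≈ 0.99).  The window is configurable for recordings with faster
drift.  *Re-centering*: PCA scores are mean-centered, so the recovered
v₁ is offset from the latent x by −mean(x), which is nonzero whenever
the animal spends unequal time in the two states.  The model's wells
cannot move off ±1, so without the midpoint subtraction the fit
compensates through β and γ; with it, the stable clusters sit at ±1 by
construction and the example "already oriented input is returned
unchanged" still holds.

## Fitting

Objective: E(t) = v₁(t) − x(t) with x simulated under the label-derived
control from (x₀, y₀) = (v₁(0), v₂(0)); the scalar objective is
Σ|E_k|·Δ with Δ the recording's frame interval.  Weighting by the
*fitted* dt instead would make the problem degenerate — shrinking dt
shrinks the "integral" without improving the fit — so the integral is
taken over the fixed recording time axis.  Only mode-1 error is
penalized; v₂ affects the fit solely through y₀.

Noise inside the objective uses common random numbers: one fixed seed
(optionally averaged over several realizations) shared by all candidate
evaluations, making the search landscape deterministic and bit-stable.
A consequence is that σ is structurally unidentifiable: against a fixed
target path, the model's own noise can only add |v₁ − x| error, so the
joint fit drives σ to ~0.  The package therefore also provides
`estimate_sigma`, which matches the observed stable-state variance of
v₁ about ±1 to the stationary variance of the linearized Euler map
(discrete Lyapunov equation, with the first 25 frames of each dwell
trimmed to drop entry transients).  On clean latents this recovers σ to
±0.01; on preprocessed latents observation noise and drift residue
inflate it by a few hundredths.

Search: uniform random search (default 500 candidates, vectorized with
a shared noise path) within bounds β ∈ (−0.9, 0.9), γ ∈ (−3, 0),
σ ∈ (0, 0.2), u₃,₄ ∈ (0, 1.5), u₅,₆ ∈ (−1.5, 0), dt ∈ (0.05, 1) —
wide brackets around the reference fits — then Nelder–Mead from the
argmin.  The simplex is *restarted* from the incumbent (up to 8 rounds
of ≤ 600 iterations, stopping when a round improves the objective by
< 0.1%): a collapsed simplex pressed against a penalty wall otherwise
stalls far from the optimum, and the landscape has a shallow valley in
(γ, u₅,₆) that a single simplex run traverses incompletely.  The
incumbent is never discarded, so the refined objective can never exceed
the starting one.

## Synthetic data

The generator inverts the preprocessing chain so that recovery is exact
by construction at zero noise: a behavioral script drives the SDE; unit-
norm random loadings map (x, y) to per-neuron *derivative* signals plus
white observation noise (sd 0.05); cumulative integration gives ΔF/F-
like traces; a multiplicative envelope exp(−t/12000 frames) emulates
photobleaching.  Defaults: 120 neurons, 3000 frames at 0.35 s — the
shape of the reference recordings.

The label script is a two-state renewal process: stable dwells of
30 + Geometric(mean 120) frames (mean 150 — the 30-frame floor prevents
a new transition from launching before the trajectory has settled),
alternating with transition windows labeled 3/4 (reversal→forward,
80 frames) or 5/6 (forward→reversal, 16 frames).  Window lengths are
set by the physics: at the reference control strengths the
reversal→forward crossing needs ~33 frames of sustained u₃,₄
deterministically and up to ~74 with noise (p99 ≈ 62), while
forward→reversal needs ~9–13; windows above those tails make the
labels basin-consistent (≥ 90%, typically ≥ 99%) the way real
annotations are.

What the generator does *not* emulate: calcium-indicator kinetics
(rise/decay filtering), non-Gaussian or correlated observation noise,
higher-dimensional latent structure (the embedding is exactly rank 2,
which is why PCA's first two modes explain ~99% of derivative variance
here versus ~20% in real recordings), neuron identity structure, and
annotation errors.  Passing the recovery tests therefore shows the
pipeline is correct and well-conditioned under the model's own
assumptions, not that real recordings satisfy those assumptions.

## Occupancy experiments

Random control uses pulses with exponential inter-arrival (mean 100
frames) and dead time equal to the pulse duration (15 frames, amplitude
±0.7 — the order of the fitted |u₅,₆|, with total impulse ~3 in model
units so most pulses complete a switch).  By default the pulse sign is
*basin-aware* — chosen at onset to push away from the currently
occupied well — which keeps the protocol symmetric at β = 0; blind
alternating signs desynchronize after a failed switch and are kept only
as an option.  Sweeps over β, σ, γ and pulse rate hold everything else
fixed, including the noise path and onset draws (common random
numbers).

Distribution summaries: occupancy fractions use a threshold of |x| >
0.5 (forward / reversal / transitional) and 50-bin histograms.  Two
spread measures are reported.  The σ effect ("variation about the fixed
points") is the std of x − sign(x) over stable-classified frames.  The
γ effect is measured as RMS distance to the nearest well over *all*
frames: stationary stable-state variance is non-monotone in damping
(with noise entering the x-equation directly, strong damping slows x's
relaxation and its variance rises again — Lyapunov calculation gives
sd(x)/σ = 1.03, 0.98, 1.05 at γ = −1, −2, −3), whereas the histogram
width that damping visibly shrinks comes from suppressing control-
driven excursions, which the all-frames measure captures robustly
(strictly monotone in 20/20 independent replicates).

## Problem sizes and tolerances

The recovery study uses 10 independent synthetic animals at the default
3000-frame, 120-neuron configuration; measured median absolute errors
are ≈ 0.05 (β), 0.16 (γ), 0.07 (u₃,₄), 0.10 (u₅,₆), 0.011 (dt).
Occupancy sweeps use 10⁵-frame runs (4×10⁵ for the β-balance check,
where the occupancy-difference estimator has sd ≈ 0.012).  Root
realness and repeated-root collapse use a 10⁻⁹ tolerance; imaginary
residue of real-argument field evaluations is discarded.  Repeated real
roots are reported once, classified "degenerate".

## Known limitations

- σ must come from moment matching, not the trajectory objective (see
  above); the fitted σ value in a `FitResult` is near the lower bound
  and should be ignored.
- γ is the least-identified dynamical parameter: its signature is the
  post-transition ringing shape, a small part of the error mass, and it
  trades off against the control strengths along a shallow valley.
- The one-step-per-frame integrator inherits O(dt) bias at the fitted
  dt ≈ 0.29; fitted parameters are therefore tied to the discretization
  (as they are in the original fitting procedure), not to the continuous
  SDE.
- Real-data ingestion (CSV/HDF5) is tested on synthetic fixtures only;
  the published .mat archives need an external conversion step.
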