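# Methods

## Model and assumptions

Regional brain activity is modeled as a linear, time-invariant, noise-free
networked system on the structural connectome: `ẋ = Ax + Bu`. The weight
matrix is symmetric, nonnegative, zero-diagonal (self-weights from
tractography are discarded on load; self-dynamics enter only through the
stabilization below). Before any control computation the adjacency is
stabilized,

    A_norm = A / (λ_max(A) + c) − I,    c > 0 (default 1),

which rescales the spectrum into (−1−ε, 0): the largest eigenvalue of
`A_norm` is exactly `−c/(λ_max + c)`, so the uncontrolled system decays.
Linearity and time-invariance are modeling choices, not claims about
neurobiology: they buy an exactly solvable transition cost and are the
standard regime for this class of connectome control analyses.

## Optimal control energy

The transition cost between states `x0` and `xT` over horizon `T` is the
minimum of `∫ (Δx'SΔx + ρ u'u) dt` subject to the dynamics and both
endpoint constraints, with `Δx = xT − x(t)`. Defaults: `S = I` (the
distance cost is unweighted), `B = I` (all regions actuated), `ρ = 1`
(input and trajectory costs weighted equally), `T = 1`. `T` is genuinely a
free model parameter; 1 is the prevailing convention for the stabilized
system and all energies are documented as `T`-dependent. The endpoint
constraint is enforced exactly (not penalized): states are initial and
target positions, and the solver reports the realized endpoint error,
flagging results infeasible above `1e-6·(1+‖xT‖)` rather than ever passing
them silently.

Pontryagin's conditions give `u* = −B'λ/(2ρ)` and a linear state/costate
system with constant forcing `2S·xT`. The solver computes one matrix
exponential of the augmented `(2N+N)`-dimensional block (propagator plus
forcing convolution), obtains `λ(0)` from a dense solve enforcing
`x(T)=xT` (erroring with a condition-number diagnostic past 1e12), and
rolls the trajectory out on a uniform grid.

Numerical choices: `n_steps = 1000` grid intervals and trapezoidal
integration of `u_i(t)²` for the per-region energies. The integration error
is `O(h²)` and sits far below the 1e-3 oracle tolerance used in
verification. The step and horizon propagators depend only on
`(A, B, S, T, ρ, n_steps)`, so they are cached and shared across all `K²`
state-pair problems of one recording; cached and uncached paths produce
bit-identical results because the cache stores exactly the arrays a fresh
computation yields.

Two independent verification routes exist. `minimum_energy` evaluates the
controllability-Gramian closed form `v'W_T⁻¹v` (Van Loan block
exponential), the cost of the cheapest input that reaches the target with
no trajectory cost — a strict lower bound, and the `ρ → ∞` limit of the
tracking solution. `direct_transcription_energy` discretizes the dynamics
exactly (zero-order hold), optimizes piecewise-constant inputs through a
sparse KKT system, and shares no code path with the TPBVP solver.

## State modeling

Recordings are z-scored per region with sample SD (ddof = 1, fixed
throughout the package); constant regions are rejected by name. Regional
series are averaged into network series; the timepoint's dominant network
is the argmax, retained only when its mean is at least the threshold
(default 0.5 SD; 0 available as the robustness variant). The threshold
applies to the signed mean — the plain reading — not its absolute value.
Exact argmax ties are discarded: breaking them by any rule would make
results depend on network ordering. State maps average the full-resolution
activity over each network's dominated timepoints; networks that never
dominate drop out of the state set and the transition tensor shrinks
accordingly.

Multi-run recordings are standardized per run and labelled per run; state
maps pool dominated timepoints across runs; transition pairs never bridge a
run boundary. Within a run the retained subsequence is treated as
contiguous — a discarded gap does not break a transition — and
`P = |retained| − 1` per run, summed across runs. Self-transitions
(consecutive timepoints dominated by the same network) are counted: the
full `K²` set of pair energies, including `i = j`, is consumed by the
average. TCE accumulates per unique ordered pair weighted by its count, so
uniformly duplicating the transition multiset leaves the map bit-identical.

The occurrence-weighted map scales each state map by the fraction of
timepoints its network dominated, dividing by total timepoints (the
default reading); a retained-only denominator sits behind a flag.

## Spatial null model

Comparing two smooth brain maps against a naive permutation null is
miscalibrated — the test suite demonstrates rejection rates several times
nominal on independent smooth fields. The surrogate null randomizes a map
while preserving its semivariogram
`γ(h) = mean over pairs at distance ~h of (v_i − v_j)²/2`, estimated in 25
equal-count distance bins with pairs beyond the 75th percentile of
inter-region distances excluded. Distances are Euclidean between region
coordinates (the desk-scale completion of surface-based distance; a
precomputed distance matrix can be supplied instead).

Each surrogate permutes the map, smooths the permutation with a Gaussian
distance kernel, and rescales: `y = mean(v) + √β(x′ − mean(x′)) + √α z`
with `z` iid standard normal and `(α, β ≥ 0)` fit by least squares aligning
the surrogate variogram to the original's. Three numerical choices matter
and were validated by measuring type-I error on independent
Gaussian-process fields (200 repetitions, 100 surrogates, 200 regions):

* kernel rows carry unit L2 norm, not unit sum — sum-normalized smoothing
  is heteroscedastic near the domain boundary and its variogram never
  saturates;
* the kernel bandwidth grid is densified at the small end
  (0.05–0.3 × max distance) — with a coarse grid the bandwidth gap is
  absorbed as spurious white noise (a fitted nugget) that narrows the null;
* the least squares is lag-weighted (`exp(−lag/(0.25·max lag))`) — spatial
  autocorrelation lives at short range, which equal-count bins otherwise
  under-represent.

With these choices the measured type-I error is 0.045–0.070 at nominal
0.05 and the surrogate variograms track the target within ~8% of its range
on average. The two-sided p-value uses the `(1 + count)/(1 + M)` estimator
(always in `(0, 1]`); surrogates are generated for the first map by
default, swappable by flag; `M = 1000` default, 10,000 for final
inference. Surrogates are bit-reproducible under a seed; equivariance
under region reordering holds in distribution but not bit-exactly, since
the permutation draw is indexed by position.

## Supporting statistics

Repeated-measures correlation is the ANCOVA common-slope model: subject
intercepts plus one shared slope, `r_rm = sign(slope)·√(SS_x/(SS_x +
SS_err))`, F-tested with `df = n − k − 1`. The implementation is plain
least squares and is verified against an independent within-subject
centering oracle (and cross-checked against pingouin). tSNR is per-run
mean/SD per region, min-max rescaled within run before averaging across
runs (that order, not the reverse). Hemisphere and age-group comparisons
delegate to scipy's Mann–Whitney, one-way ANOVA and Levene tests.

## Synthetic data

The generators produce everything the pipeline consumes, as pure functions
of a spec and seed, each with a ground-truth ledger sufficient for
downstream oracles. Connectomes are modular: edges appear with a density
(default 0.3) and exponential weights whose mean is larger within network
blocks (1.0) than between (0.5). Recordings place, at each timepoint, the
dominating network's template (amplitude 1.0 on its regions, 0 elsewhere)
plus iid Gaussian noise (SD 0.1 of amplitude); timepoints planted as
discarded are pure noise (15% by default). Reference maps are
Gaussian-process draws with squared-exponential covariance (lengthscale 20
in a 100-unit box). Default scale is 60 regions in 4 networks (2 unimodal,
2 heteromodal) over 200 timepoints — enough transition structure for
nontrivial counts at seconds-level test runtime; the seven-network variant
mirrors the canonical partition at any region count.

What the generator does not emulate: hemodynamics, temporally
autocorrelated or spatially structured fMRI noise, tractography biases, or
any realistic geometry of the cortical sheet. Passing tests therefore show
that the pipeline's logic and statistics behave correctly under its own
model assumptions; they do not certify effect sizes on real recordings,
where state dominance is far less clean than a planted template.

## Verification problem sizes

The verification suite solves its control problems at N ∈ {1, …, 16}
regions (20 random systems against the transcription oracle on a
2000-point grid), recovery at the default 60-region/200-timepoint scale
over 20 seeds, and null-model calibration at 200 regions with 100
surrogates and 200 repetitions — sizes at which every check completes in a
few minutes on a single CPU while leaving the statistical assertions
well-powered.

## Known limitations

Energies depend on the unstated horizon `T`; comparisons are only
meaningful at fixed `T`. The dominance model quantizes brain activity to
one winner per timepoint and discards sub-threshold timepoints, trading
temporal granularity for robustness. Euclidean inter-region distance
understates geodesic cortical distance, which slightly distorts variograms
of surface-derived maps; supplying a geodesic distance matrix is supported.
The Gramian route requires a controllable pair; with `B = I` this always
holds, but heavily restricted control sets can make the Gramian numerically
singular, which is reported rather than regularized.
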