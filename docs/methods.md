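# Methods

## Model

Counts are modeled per genomic window (0-based, half-open, constant width;
500 bp is the default and suits broad marks, 250 bp short marks).  A single
stationary 3-state hidden Markov chain runs along the windows of the
genome: consensus background (state 1), differential (state 2), consensus
enrichment (state 3).  Emissions are negative binomial in mean/dispersion
form, `Var = μ(1 + μ/φ)`, independent across samples given the state.  The
differential state is a finite mixture over all `L = 2^G − 2` non-empty,
non-full condition subsets; component `l` applies the enriched GLM level
exactly to the conditions in `S_l` through the binary design column
`x_l`.  Patterns are ordered canonically by (cardinality, lexicographic),
which fixes the indexing of the mixture proportions `δ`.

Key assumptions, and what they buy:

- **Shared GLM parameters across states and components.**  One
  `(β₁, β₃, λ₁, λ₃)` describes background and enriched levels everywhere.
  This pools information across the genome (rare patterns remain estimable)
  and reduces the M-step to a single weighted NB regression.  It also means
  per-condition systematic differences must be absorbed by the offsets, not
  by free means.
- **`β₃ > 0`** (enforced by optimizing `log β₃`): enrichment means more
  signal than background, which pins the state labels and prevents
  label switching.  `λ₃` is unconstrained — dispersion may move either way.
- **Offsets are inputs.**  `u_hij` enters the log-mean additively.  All-zero
  by default; `library_size_offsets` provides per-sample depth offsets
  (log total over geometric mean, zero-sum).  Estimating nonlinear offsets
  (GC content, input controls) is out of scope; precomputed offsets plug in.

## Estimation

EM with exact E-steps: scaled forward–backward for the state posteriors
`ρ`, pairwise posteriors `ξ` and the observed-data log-likelihood, and a
softmax over `log δ_l + log f_{2,l}` for the mixture posteriors `w`.
M-step: `π̂ = ρ₁`, `γ̂_rs = Σξ/Σρ`, `δ̂_l = Σ ρ_{j2} w_{jl} / Σ ρ_{j2}`,
and a pooled weighted NB regression for the GLM: each (window, sample)
contributes a covariate-0 observation with weight `ρ_{j1}`, a covariate-1
observation with weight `ρ_{j3}`, and per component `l` an observation with
covariate `x_{hl}` and weight `ρ_{j2} w_{jl}`.  The regression is maximized
by L-BFGS with analytic gradients; convergence at gradient max-norm 1e-6 or
relative objective change 1e-10, warm-started from the previous iterate.

Two devices keep genome-scale fits fast:

- **Aggregation.**  The (count, offset, covariate) triples of the
  pseudo-observations do not change across iterations, so their grouping is
  computed once and each M-step reduces weights by a bincount; windows with
  identical count configurations collapse to one regression record.
- **Rejection control (RCEM).**  Before building regression weights, each
  per-window state occupancy `p < c` (threshold `c = 0.05`) is set to `c`
  with probability `p/c` and to 0 otherwise; `p ≥ c` is untouched.  The
  adjustment is unbiased and zeroes most of the genome out of the
  regression.  Chain updates (`π, γ, δ`) always use unadjusted posteriors.
  Rejection control is applied to each of the three states' occupancies.

**Numerical choices.**  Within `em_fit` the rejection draws reuse one
uniform per (window, state) across iterations (common random numbers).
Per-iteration unbiasedness is unchanged, but accept/reject decisions
stabilize as the posteriors converge; with fresh draws the Monte-Carlo
jitter on the weakly identified `λ₃` (≈1% relative at 10⁵ windows) keeps
the convergence rule from ever firing.  The standalone `rejection_control`
operation draws fresh randomness from its seeded generator.  Probabilities
are floored at 1e-300 before logs; mixture and emission sums use
logsumexp; Viterbi ties break toward the lower state index.

**Convergence.**  The fit stops when the maximum absolute relative change
of every parameter in `Ψ = (π, γ, δ, β₁, β₃, λ₁, λ₃)` between iterations
`t` and `t−3` is below 1e-3 for three consecutive `t` (denominator floored
at 1e-8), or at `max_iter = 500` with `converged=False`.  With RCEM off the
log-likelihood trace is non-decreasing (standard EM monotonicity); with
RCEM on, small stochastic decreases are possible by construction.

**Initialization** (the model's likelihood is multimodal, so this matters):
windows ranked by total count seed the states — bottom 40% background, top
10% enrichment — and the NB background parameters are moment-matched on the
seed groups.  `β₃` comes from the ratio of seed-group means; `λ₃` starts at
0 rather than moment-matched, because the top group mixes fully and
partially enriched windows, and its inflated variance otherwise starts the
enriched dispersion far too low and can trap EM in a mode where consensus
enrichment swallows the differential windows.  `π = (0.8, 0.1, 0.1)`, `γ`
diagonal 0.97, `δ` uniform.  A degenerate start (a state with essentially
zero occupancy after the first E-step) triggers one deterministic retry
with 30%/20% seed groups.

**Model selection.**  `BIC = −2·loglik + p·log M` with
`p = 2 (π) + 6 (γ) + (L−1) (δ) + 4 (GLM)`; this free-parameter count is a
convention and is documented rather than canonical.  `prune_components`
iteratively removes the smallest-`δ̂` component while it is below the 0.05
floor, renormalizes, refits, and returns the minimum-BIC model (never below
one component).

## Peak calling and classification

The posterior `ρ̂_{j2}` of the differential state is thresholded by the
total-FDR rule: ranking windows by `ρ̂_{j2}`, the call set is the largest
prefix whose mean posterior error `1 − ρ̂_{j2}` is at most the nominal
level (default 0.05).  Windows tied with the boundary value are included
only if the constraint still holds with all of them, else all excluded —
deterministic either way.  Contiguous called windows (same chromosome,
abutting coordinates) merge into peaks; `viterbi-extend` mode additionally
grows each called window through its surrounding run of
differential-Viterbi windows.  Each peak's pattern label is the argmax of
the member-window average mixture posterior, ties (within 1e-9, which
absorbs float summation order) toward the lower canonical index.  The FDR
call set is authoritative: a peak's extent never depends on the Viterbi
path except in `viterbi-extend` mode.

## Simulator

The generator emulates the window-count level of a multi-condition
experiment: a first-order Markov chain over all `2^G` background/enrichment
configurations, NB emissions per sample given the window's configuration.
Collapsing configurations (all-background → state 1, all-enriched →
state 3, else state 2) yields the 3-state truth used for benchmarking, so
the generating process is deliberately *not* the fitted model — the fitted
model sees `2^G` configurations through a 3-state lens.

Defaults are the study conditions used throughout: the ENCODE-derived
H3K27me3 GLM truth `(β₁, β₃, λ₁, λ₃) = (1.116, 1.165, 1.281, 0.124)`
(enrichment/background mean ratio `exp(1.165) ≈ 3.21`), `G = 2`, one
replicate, 10⁵ windows of 500 bp.  The configuration chain is
`P = s·I + (1−s)·1ν'` with persistence `s = 0.95` and stationary
distribution `ν` = 85% all-background, 10% differential (split evenly),
5% all-enriched: `ν` is exactly stationary by construction, every
configuration's self-transition is ≥ 0.95 (mean run length ≥ 20 windows,
i.e. ≥ 10 kb blocks), and the differential fraction is in the range typical
of broad-mark contrasts.  `snr_adjust` retargets the mean ratio while
keeping the enriched variance-to-mean ratio `1 + μ/φ` fixed (dispersion
scales with the mean) and leaving the background level untouched.

What the simulator does **not** emulate: GC-content and mappability biases,
input-control structure, fragment-level read placement, duplicate reads,
copy-number variation, or unequal library sizes (a per-sample depth offset
can be added explicitly).  Passing recovery and FDR tests on these
simulations therefore demonstrates correctness of the estimation and
calling machinery under the count model, not robustness to real-data
artifacts — on real data those artifacts must be handled through the
offsets.

## Problem sizes and tolerances in the tests

The recovery study runs 8–10 datasets of 10⁵ windows (the package's chosen
benchmark scale; recovery bias is insensitive to the window count, so more
windows only shrink Monte-Carlo spread).  At this scale the per-dataset
relative-bias spread is roughly 0.002 (β₁), 0.007 (λ₁) and 0.1–0.3 (λ₃ —
a small parameter, |λ₃| = 0.124, hence large relative noise), so tests
assert mean biases within near-zero envelopes (±0.001 β₁, ±0.004 λ₁)
inflated by twice the empirical standard error of the mean, and treat λ₃
with correspondingly wider bounds.  Exact-inference tests compare
forward–backward and Viterbi against brute-force enumeration of all `3^M`
paths at `M ≤ 6` (tolerance 1e-10).  The realized window-level FDR on
well-specified simulations is checked against the nominal 0.05 with an
allowance of 0.03 for Monte-Carlo error under along-genome posterior
correlation.

## Known limitations

- One latent chain genome-wide: no per-chromosome stratification of `π`/`γ`
  (windows of all chromosomes are concatenated in coordinate order).
- Shared `(β₁, β₃, λ₁, λ₃)` means strong per-condition mean shifts must be
  normalized away via offsets before fitting.
- `λ₃` is weakly identified at small genome sizes; its estimate should be
  read with the spread reported by `recovery_experiment`, not as a point
  value.
- `G ≤ 8` (the mixture has `2^G − 2` components).
- Missing windows are not supported; the window grid must be constant-width
  and sorted.
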