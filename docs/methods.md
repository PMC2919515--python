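# Methods

## Model and assumptions

Two object populations live in a bounded planar region Ω: query points
X = {x_i} and reference objects Y = {y_j} (points or simple closed
polygons). The analysis rests on three assumptions shared with classical
object-based co-localization: spatial homogeneity and isotropy of the
interaction inside Ω, and exclusively nearest-neighbor coupling between the
two populations (each x interacts only with its nearest y). Under these
assumptions the signed nearest-neighbor distances d_i are i.i.d. with
density

    p(d) = q(d) exp(−φ(d)) / Z,      Z = ∫ q exp(−φ) dd,

where q(d) is the state density of the context {Ω, Y} and φ the effective
pairwise potential. φ is an *effective* quantity: it absorbs every process
that shapes the observed pattern, so fitted values support relative
comparisons (between strains, over time) rather than direct biophysical
interpretation.

Signed distance convention: d < 0 strictly inside a polygonal reference,
0 on the outline (tolerance 1e-9 px), Euclidean otherwise. Coordinates are
continuous pixels with the origin at the image corner; mask pixel (r, c)
spans [c, c+1) × [r, r+1). When outlines overlap, the signed minimum is
taken, i.e. an enclosed point reports the most negative value. Only
point-to-object distances are needed; reference-to-reference distances
never enter the model.

## State density estimation

q is measured exhaustively: a cell-centered Cartesian grid (spacing
h = 0.25 px by default; offset h/2 so each sample represents an equal-area
tile) is clipped to Ω, signed NN distances are computed for every grid
point, and a Gaussian kernel density estimate is formed. The bandwidth
default is the normal-reference (Silverman) rule on the grid sample,
mirroring a default-settings Gaussian KDE. The KDE is computed in binned
form on the 1024-point output grid (binning error is orders of magnitude
below the bandwidth at this resolution); the support is extended by three
bandwidths beyond the empirical range and the density renormalized to unit
trapezoid integral. Values near the support edges are smoothing artifacts
and should be interpreted cautiously. Halving h from 0.5 to 0.25 changes
baseline co-localization values by well under 1% on smooth contexts (tested).

All downstream integrals (Z, model density, likelihood, CDF inversion for
sampling) share q's 1024-point grid, so they are mutually consistent to
machine precision on one discretization. One exception is deliberate: for
the discontinuous step potential, Z and the sampler split the integral
exactly at the threshold via the trapezoid CDF instead of integrating
through the jump, which keeps the partition function and the co-localization
baseline consistent to machine precision rather than O(grid step).

## Potential families

All shapes follow the attractive convention f ≤ 0, depth −1 near the
origin, f(+∞) = 0 (the model is invariant to adding a constant to φ, so
anchoring at zero is a pure gauge choice):

| family    | f(z)                                      | character |
|-----------|-------------------------------------------|-----------|
| step      | −1 (z < 0), 0 (z ≥ 0)                      | classical threshold co-localization |
| plummer   | −1 (z ≤ 0), −1/√(1+z²) (z > 0)             | step generalization: plateau below 0, smooth 1/z tail, C¹ everywhere |
| hermquist | −1+z (z < 0), −1/(1+z) (z ≥ 0)             | slow 1/z decay, C¹ at 0; long-range shape |
| linear1   | min(z−1, 0)                                | linear rise, no plateau |
| linear2   | clip(z−1, −1, 0)                           | step with a linear ramp and plateau |

The non-parametric potential is a weighted sum of triangular (hat) kernels
on P = 21 equally spaced support points from −5 to 95 px (spacing 5 px),
i.e. the piece-wise linear interpolant through (d_p, w_p); w_P = 0 pins
φ = 0 at and beyond the last support point, and φ is clamped to w_1 below
the first.

## Inference

**Step potential (exact).** C^t counts d_i < t strictly (ties at t do not
co-localize, matching the integral ∫_{d<t}). The strength estimator is the
log odds ratio ε̂ = ln[C(1−C0)/(C0(1−C))]; degenerate cases (C ∈ {0,1} or
C0 ∈ {0,1}) are returned as explicit status flags, never as raw floating
infinities. Under H0, N·C^t ~ Binomial(N, C0), giving exact critical
counts (smallest k with upper-tail probability ≤ α) and exact power under
the step alternative p1 = C0 e^a / (C0 e^a + 1 − C0).

**General shapes (Monte Carlo).** The model is an exponential family in ε,
so T = −Σ_i f((d_i−t)/σ) is sufficient; larger T means stronger attraction
(for the step shape T is exactly the co-localization count). The one-sided
rank test draws K null samples of N distances from q by inverse-CDF
sampling, and rejects when the observed T exceeds the ⌈(1−α)K⌉-th null
order statistic; the matching MC p-value is (1 + #{T_k ≥ T_obs})/(K+1),
with ties counted against rejection. Repulsion detection (lower tail) is
deliberately out of scope. The shape-free variant bins distances into
L = 20 equal-width bins spanning q's non-zero range, estimates the null
moments (E0, Cov0) from a first MC sample, forms the Mahalanobis statistic
U = (T−E0)ᵀ Cov0⁻(T−E0) with a Moore–Penrose pseudo-inverse (cutoff 1e-10;
empty bins therefore cannot crash the test), and ranks U in a second,
independent MC sample — the two stages use separate spawned RNG streams,
since reusing the moment sample for ranking would bias the test.

**Power and minimal N.** Power is the rejection fraction over simulated
datasets drawn from p(d | q, φ_true); defaults K = 199, 200–300 replicates
keep desk-scale runtimes while giving a binomial standard error of ~0.02
near 80% power. The minimal sample size for a target power is found by
doubling then bisection in N; MC noise in the power estimates propagates
into the reported N (the bracketing interval is returned).

**Maximum likelihood.** l(Θ|D) = Σ_i [log q(d_i) − φ(d_i)] − N log Z on
q's grid; distances outside q's support are a hard error (no silent
clamping), and interpolated q is floored at 1e-300 inside the support to
avoid −inf from underflow. The 1-D strength MLE uses bounded Brent search
(the likelihood is concave in ε); standard errors come from the numerical
observed information. The per-cell 2-D fit optimizes (ε, log σ) —
positivity enforced by the log parameterization — with Nelder–Mead
multi-started from σ ∈ {0.5, 2, 8} px; a "weakly_identified" status flags
the ridge that appears when ε ≈ 0 and σ becomes arbitrary. The pooled fit
estimates one σ* shared by all cells with cell-specific strengths by nested
optimization: bounded 1-D search over log σ*, each evaluation solving the
inner per-cell strength MLEs; it proceeds when ≥ 80% of inner fits
converge and reports AIC = 2k − 2l* and BIC = k ln(ΣN_k) − 2l* with
k = N_cells + 1. Tolerances: 1e-6 relative on objectives, 1e-4 on
parameters, ≤ 500 outer iterations.

**Non-parametric fit.** The penalized joint log-likelihood
Σ_k l(w|D_k) − Σ_{p<P} (w_p−w_{p+1})²/(2s²) (a Gaussian prior with sd
s = 2 on successive weight differences) is strictly concave in w — log Z is
convex in the weights and the penalty is quadratic — so it is maximized by
L-BFGS-B with the analytic gradient, which reaches the global optimum; a
restarted quasi-Newton multi-start serves as an oracle in the tests. One
identifiability caveat is intrinsic to the model: the likelihood is exactly
invariant under φ → φ + c, so the overall *level* of the fitted potential
is pinned only by the w_P = 0 anchor propagated through the smoothness
prior. When the data cover only part of the support grid, the level
wanders by O(1) between replicates while the gauge-invariant *shape*
(differences of weights over the data-covered range) is stably recovered;
tests therefore judge shrinkage and recovery on the variation of φ, not on
absolute weight values.

**Time courses.** Per-cell strengths against a covariate (e.g. minutes
post infection) are smoothed by Nadaraya–Watson regression with a Gaussian
kernel (default bandwidth 5 min); the band is the same-weights local
standard deviation of the estimates — it describes scatter, not a formal
confidence interval, and no between-group test is attached.

## Synthetic scenarios

The generator emulates the benchmark context used throughout: M = 100
circles of radius R = 3.57 px in a 200 × 200 px square, the radius chosen
so the nominal covered area fraction M·πR²/area is 0.1 (circles may
overlap in "random" mode; the nominal fraction ignores overlap, which is
what makes the printed R arithmetic exact). Circles are rendered as
64-gons (radial error R(1 − cos(π/64)) ≈ 1.2e-3 R). "Regular" placement
perturbs a square lattice (jitter sd = 5% of the lattice spacing; rejected
if the spacing cannot fit a circle diameter) and "clustered" uses a
Thomas-style parent/offspring process (10 parents, offspring sd 10 px,
wrapped into the domain) — the last two are explicit stand-ins for
qualitative context effects, as no canonical definition exists. Query
points are placed by exact rejection sampling of the factorized model:
uniform proposals in Ω accepted with probability exp(−(φ(d) − φ_min)),
with φ_min bounded over the achievable distance range; the sampler aborts
with guidance if the acceptance rate falls below 1e-4.

What the generator does *not* emulate: segmentation errors, localization
noise, chromatic aberration, 3D-to-2D projection distortion, within-set
interactions of the reference objects, and position-dependent potentials.
Passing tests on synthetic data therefore demonstrate correctness of the
statistical machinery under the model's own assumptions, not robustness to
the imaging artifacts real data carry.

## Problem sizes and defaults

Defaults follow the benchmark conditions: grid spacing h = 0.25 px,
L = 20 bins, α = 0.05, t = 0, P = 21, s = 2, K = 999 for single tests,
K = 199 with 200–300 replicates for power studies, N cap 4096 in the
minimal-N search. The acceptance script runs the 500-replicate calibration
and the two minimal-N searches in under a minute on one CPU; the state
density of the benchmark context (640 000 grid samples against 100
64-gons) takes a few seconds. All randomness flows through
numpy Generators seeded from a single SeedSequence, so every result is
reproducible bit-for-bit given the seed.

## Known limitations

- The effective potential confounds all pattern-generating processes;
  absolute parameter values are not biophysical constants.
- q estimation assumes the reference objects occupy the domain densely
  enough; large empty regions make q (and everything downstream) fragile.
- The non-parametric potential's level (not shape) is weakly identified
  off-support, as discussed above.
- One-sided (attraction) tests only; repulsion would need the lower tail.
- 2D only; the model generalizes to 3D but the geometry layer here does not.
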