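# interpot — object-based spatial interaction analysis

`interpot` infers *effective pairwise interaction potentials* between two
populations of sub-cellular objects from microscopy-derived object
representations: query points **X** (e.g. virus centroids) and reference
objects **Y** (points or closed polygonal outlines, e.g. endosomes) inside a
bounded cell region Ω. It is aimed at quantitative cell biologists and image
analysts who want to go beyond threshold co-localization percentages and ask:
*how strong is the association, over what distance range does it act, and is
it statistically distinguishable from the geometry of the cell alone?*

## The model

The basic datum is the signed nearest-neighbor distance
d(x) = min_j d(x, y_j), negative when x lies inside a reference outline. Two
quantities carry all the information:

- the **state density** q(d) — the distribution of d for a *uniformly random*
  position in Ω given the reference configuration. It summarizes the cellular
  context (object density, sizes, placement, domain shape) and is the null
  model "no interaction". It is measured by exhaustive sampling of Ω on a
  Cartesian grid (default spacing h = 0.25 px) followed by Gaussian kernel
  density estimation.
- the **interaction potential** φ(d) = ε·f((d − t)/σ), with strength ε
  (ε > 0 ⇒ attraction), shape f, range σ, and shift t. Under the factorized
  Gibbs model the observed distances are i.i.d. with density

  p(d) = q(d) · exp(−φ(d)) / Z,  Z = ∫ q(u) exp(−φ(u)) du.

Classical object-based co-localization is the special case of a step-shaped
φ: the measure C^t (fraction of distances below t), corrected by its
baseline C0^t = ∫_{d<t} q, yields the closed-form strength estimator
ε̂ = ln[C(1−C0) / (C0(1−C))], with exact binomial tests and power analysis.
For general shapes, inference uses the sufficient statistic
T = −Σ_i f((d_i − t)/σ) with Monte-Carlo rank tests, MC power estimation and
minimal-sample-size search; parameters are estimated per cell, or jointly
across cells with a shared scale σ* (nested maximum likelihood), and a
penalized piece-wise linear potential can be fitted without assuming any
shape. Everything is testable without microscopy data through the built-in
synthetic scenario generator (circles in a square domain, points placed by
exact rejection sampling under a chosen potential).

## Worked example

```python
import interpot as ip

# a synthetic cell: 100 circles (R = 3.57 px) in a 200 x 200 px domain,
# query points placed under a long-ranged Plummer attraction
truth = ip.Potential("plummer", epsilon=1.0, sigma=5.0, t=0.0)
spec = ip.ScenarioSpec(M=100, R=3.57, N=150, true_potential=truth, seed=3)
cell = ip.generate_scenario(spec)

res = ip.analyze_coloc(cell.D, cell.q, t=0.0)
print(res.C, res.C0, res.epsilon_hat.value)

matched = ip.mc_rank_test(cell.D, cell.q, "plummer", sigma=5.0, K=999, seed=1)
step = ip.mc_rank_test(cell.D, cell.q, "step", K=999, seed=1)
print(matched.p_value, step.p_value)
```

Output (from `examples/03_mc_testing.py`, which this condenses):

```
matched Plummer statistic     : T_plummer =  109.312  p = 0.0010  reject H0: True
mismatched step statistic     : T_step    =   18.000  p = 0.1930  reject H0: False
```

The same 150 distances reject "no interaction" decisively when tested with
the statistic matched to the true long-ranged shape, but not with the step
statistic that underlies classical co-localization — the mismatch costs
roughly a factor of four in required sample size (see
`scripts/acceptance.py`). The `examples/` directory contains one short
narrative script per capability: state-density estimation, corrected
co-localization with exact binomial power, MC testing, parametric and pooled
fitting with model ranking, and non-parametric potential estimation with
time-course smoothing. A thin CLI (`interpot simulate|qdensity|coloc|test|
fit|fit-np|power`) wraps the same functions for shell use.

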