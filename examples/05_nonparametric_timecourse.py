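"""Non-parametric potential estimation and time-course smoothing.

First a piece-wise linear potential is estimated from pooled cells without
assuming any shape — the template one would use to pick a parametric
family.  Then a simulated time course of per-cell strengths (a transient
association, e.g. cargo passing through a compartment) is smoothed with the
Nadaraya-Watson kernel estimator.
"""

import numpy as np

import interpot as ip

rng = np.random.default_rng(8)
spec = ip.ScenarioSpec(domain_size=(120.0, 120.0), M=36, R=3.57, N=10, seed=8)
Y, domain = ip.generate_circles(spec)
q = ip.estimate_state_density(domain, Y, grid_spacing=0.5)

truth = ip.Potential("hermquist", 3.0, 4.0, 0.0)
cells = [ip.CellData(f"c{j}", ip.sample_distances(q, truth, 600, seed=rng), q, {})
         for j in range(4)]
pot = ip.fit_nonparametric(cells)
print("non-parametric potential (support point: fitted vs true):")
for p in range(0, 8):
    d = pot.support_points[p]
    print(f"  d = {d:5.0f} px   phi_hat = {pot.weights[p]:6.2f}   phi_true = {truth(d):6.2f}")
print("-> the hat-kernel estimate sketches depth and range without assuming "
      "a shape (the overall level is only weakly identified)")

# simulated time course: strength rises and falls over ~45 min
t_obs = np.sort(rng.uniform(2, 46, 60))
eps_t = 3.0 * np.exp(-0.5 * ((t_obs - 20.0) / 10.0) ** 2) + rng.normal(0, 0.3, 60)
tq, mean, sd = ip.kernel_smooth(t_obs, eps_t, bandwidth=5.0)
peak = tq[np.argmax(mean)]
print(f"\ntime course: smoothed strength peaks at {peak:.1f} min "
      f"(simulated peak at 20 min)")
print(f"peak height {mean.max():.2f} +- {sd[np.argmax(mean)]:.2f} (local sd band)")
print("-> kernel smoothing turns noisy per-cell estimates into an "
      "interpretable association kinetic")
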