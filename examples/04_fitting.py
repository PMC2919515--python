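"""Maximum-likelihood potential fitting and model ranking across cells.

Simulates a batch of cells sharing one interaction range but with
cell-to-cell strength variability, then (i) fits each cell jointly,
(ii) fits all cells with a common scale sigma* by the nested pooled MLE,
and (iii) ranks candidate potential families by pooled log-likelihood.
"""

import numpy as np

import interpot as ip

rng = np.random.default_rng(5)
spec = ip.ScenarioSpec(domain_size=(120.0, 120.0), M=36, R=3.57, N=10, seed=5)
Y, domain = ip.generate_circles(spec)
q = ip.estimate_state_density(domain, Y, grid_spacing=0.5)

sigma_true = 4.0
cells = []
for k in range(8):
    eps_k = float(1.5 + rng.random())
    D = ip.sample_distances(q, ip.Potential("hermquist", eps_k, sigma_true, 0.0),
                            500, seed=rng, cell_id=f"cell{k}")
    cells.append(ip.CellData(f"cell{k}", D, q, {"eps_true": eps_k}))

one = ip.fit_cell(cells[0].D, q, "hermquist")
print(f"single-cell joint fit: eps = {one.epsilon:.2f} +- {one.stderr_epsilon:.2f}, "
      f"sigma = {one.sigma:.2f} +- {one.stderr_sigma:.2f} "
      f"(true eps = {cells[0].covariates['eps_true']:.2f}, sigma = {sigma_true})")

pooled = ip.fit_pooled(cells, "hermquist")
print(f"pooled fit over {len(cells)} cells: sigma* = {pooled.sigma_star:.2f} "
      f"({pooled.n_params} parameters, loglik = {pooled.pooled_loglik:.1f})")
print("-> pooling stabilizes the shared range; strengths stay cell-specific")

print("\nmodel ranking by pooled log-likelihood (truth is hermquist):")
fits = {fam: ip.fit_pooled(cells, fam) for fam in
        ("hermquist", "linear1", "linear2", "plummer", "step")}
for rank, (fam, f) in enumerate(
        sorted(fits.items(), key=lambda kv: -kv[1].pooled_loglik), start=1):
    print(f"  {rank}. {fam:10s} loglik = {f.pooled_loglik:10.1f}  AIC = {f.aic:9.1f}")
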