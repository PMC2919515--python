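"""Monte-Carlo rank tests: matched, mismatched, and shape-free.

A long-ranged Plummer attraction is planted.  Three tests are run on the
same data: the matched Plummer statistic, the shape-mismatched step
statistic (classical co-localization), and the non-parametric binned test.
The matched statistic extracts the most evidence.
"""

import interpot as ip

truth = ip.Potential("plummer", 1.0, 5.0, 0.0)
spec = ip.ScenarioSpec(domain_size=(200.0, 200.0), M=100, R=3.57, N=150,
                       true_potential=truth, seed=3)
cell = ip.generate_scenario(spec, grid_spacing=0.5)
print(f"planted: Plummer attraction, strength {truth.epsilon}, range sigma = {truth.sigma} px")

for label, run in [
    ("matched Plummer statistic",
     lambda: ip.mc_rank_test(cell.D, cell.q, "plummer", sigma=5.0, K=999, seed=1)),
    ("mismatched step statistic",
     lambda: ip.mc_rank_test(cell.D, cell.q, "step", sigma=1.0, K=999, seed=1)),
    ("non-parametric binned test",
     lambda: ip.nonparametric_test(cell.D, cell.q, L=20, K=999, seed=1)),
]:
    res = run()
    print(f"{label:30s}: {res.statistic_name} = {res.observed:8.3f}  "
          f"p = {res.p_value:.4f}  reject H0: {res.reject}")

print("-> smaller p for the matched statistic: knowing the interaction shape "
      "buys detection power; the shape-free test trades power for generality")
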