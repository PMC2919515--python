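"""The state density q(d): what 'no interaction' looks like in a given context.

Builds a synthetic cell — circular reference objects in a square domain —
and measures the null distribution of nearest-neighbor distances by
exhaustive grid sampling.  The baseline co-localization C0 is the fraction
of co-localized objects expected from geometry alone.
"""

import interpot as ip

spec = ip.ScenarioSpec(domain_size=(200.0, 200.0), M=100, R=3.57, seed=42)
Y, domain = ip.generate_circles(spec)
print(f"context: {spec.M} circles of radius {spec.R} in a "
      f"{spec.domain_size[0]:.0f} x {spec.domain_size[1]:.0f} px domain")
print(f"nominal circle-covered area fraction: {ip.nominal_covered_fraction(spec):.4f}")

q = ip.estimate_state_density(domain, Y, grid_spacing=0.25)
lo, hi = q.support
print(f"q(d) support: [{lo:.2f}, {hi:.2f}] px  (negative = inside a circle)")
print(f"KDE bandwidth (normal-reference rule): {q.bandwidth:.3f} px")

C0 = ip.baseline_coloc(q, t=0.0)
print(f"baseline co-localization C0 (t=0): {C0:.4f}")
print("-> even with zero interaction, ~{:.1f}% of uniformly placed points "
      "fall inside a circle purely because circles cover that much area".format(100 * C0))
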