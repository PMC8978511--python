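"""Fit the stringency-aware negative-binomial gravity model (CGM).

The mean flow is exp(eps + alpha*log P_i + beta*log P_j + gamma*log r
+ delta1*SI_i + delta2*SI_j): a gravity surface whose level responds to the
origin's and destination's policy stringency.  Negative delta means
restrictions suppress travel.
"""

import mobiflux as mf
from mobiflux.cgm import delta_z_scores

config = mf.SynthConfig(n_countries=30, n_days=60, seed=6)
world = mf.generate_world(config, seed=6)
truth = mf.CGMTruth(alpha=0.8, beta=0.7, gamma=-1.5, delta1=-0.02, delta2=-0.03)
sim = mf.simulate_flows(world, truth, noise=mf.NoiseSpec("negative_binomial", 5.0),
                        seed=7, direction="both")

design = mf.build_design(sim.panel, world.locations, world.stringency, "power",
                         distances=world.distances)
params = mf.cgm_fit(design)

print(f"{'coefficient':<12}{'truth':>10}{'fitted':>10}{'std err':>10}")
for name in ("alpha", "beta", "gamma", "delta1", "delta2"):
    print(f"{name:<12}{sim.truth[name]:>10.4f}"
          f"{params.coefficients()[name]:>10.4f}"
          f"{params.standard_errors[name]:>10.4f}")
print(f"dispersion   {5.0:>10.2f}{params.dispersion:>10.2f}")
z = delta_z_scores(params)
print(f"\nWald z for the stringency effects: delta1 {z['delta1']:.1f}, "
      f"delta2 {z['delta2']:.1f} — both clearly below -2, so the fitted "
      "model attributes the flow decline to rising stringency.")
print("delta2 = -0.03 means 10 extra stringency points at the destination "
      f"multiply expected flows by {2.718281828**(-0.3):.2f}.")
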