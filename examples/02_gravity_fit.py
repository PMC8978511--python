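"""Fit a gravity model and recover the parameters that generated the data.

Flows follow T_ij = K * m_i * m_j * exp(-beta * r_ij) plus Poisson noise;
nonlinear least squares on the raw flows should give beta back.
"""

import mobiflux as mf

config = mf.SynthConfig(n_countries=30, n_days=10, seed=2)
world = mf.generate_world(config, seed=2)
truth = mf.GravityTruth(kind="exponential", beta=0.005)  # 1/km
sim = mf.simulate_flows(world, truth, noise=mf.NoiseSpec("poisson"), seed=3,
                        direction="incoming")

fit = mf.gravity_fit(sim.panel, world.locations, "exponential",
                     distances=world.distances)
print(f"true beta      : {truth.beta:.6f} /km")
print(f"fitted beta    : {fit.spec.beta:.6f} /km  "
      f"({100 * (fit.spec.beta / truth.beta - 1):+.2f}% off)")
print(f"fitted scale K : {fit.scale:.3e}  (true {sim.truth['scale']:.3e})")
print(f"residual norm  : {fit.residual_norm:.3e} over {fit.n_obs} observations")
print("\nbeta is the distance-decay rate: flows drop by a factor e every "
      f"{1 / fit.spec.beta:.0f} km.")
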