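"""Radiation-model predictions: parameter-free flows from populations and
intervening opportunities.

The flow score from i to j depends only on the two populations and s_ij, the
population living closer to i than j is.  Scaling scores to an origin's
observed daily total turns them into absolute flows.
"""

import mobiflux as mf

config = mf.SynthConfig(n_countries=10, n_days=5, seed=4)
world = mf.generate_world(config, seed=4)
locs = world.locations

s = mf.intervening_population("HUB", "C005", locs, world.distances)
print(f"intervening population between HUB and C005: {s:,.0f} persons")
print(f"(distance {world.distances['HUB', 'C005']:.0f} km; everyone living "
      "inside that circle around the hub, endpoints excluded)")

sim = mf.simulate_flows(world, mf.GravityTruth(), noise=mf.NoiseSpec("poisson"),
                        seed=5, direction="outgoing")
totals = mf.aggregate_daily_total(sim.panel, "outgoing", "HUB")
pred = mf.radiation_star_predict(locs, totals, "outgoing",
                                 distances=world.distances)
day1 = pred[pred["date"] == config.start].nlargest(3, "flow")
print("\ntop 3 predicted outflows on day 1 (scaled to the observed total):")
print(day1[["destination", "flow"]].to_string(index=False))
print(f"\npredicted flows per day sum to the observed daily total "
      f"({totals.iloc[0]:,.0f} on day 1) — there is nothing to calibrate.")
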