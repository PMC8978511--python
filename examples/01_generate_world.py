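"""Generate a synthetic study world and look at its pieces.

A world is a hub-and-spoke network of countries: one hub exchanging daily
flows with each counterpart, log-normal populations, centroid geometry, and
per-country stringency trajectories that ramp up from an intervention date.
"""

import mobiflux as mf

config = mf.SynthConfig(n_countries=8, n_days=30, seed=1)
world = mf.generate_world(config, seed=1)

print("locations (hub first):")
print(world.locations.df.head(4).to_string())
print(f"\nhub: {world.locations.hub_id}; distances in km, e.g. "
      f"HUB->C001 = {world.distances['HUB', 'C001']:.0f} km")

si = world.stringency.df
c1 = si[si["location"] == "C001"].set_index("date")["si"]
print("\nstringency trajectory of C001 (0 = no restrictions, 100 = max):")
print(c1.iloc[::6].to_string())
print("\nThe index is 0 until the country's intervention date, climbs "
      "linearly over the ramp, then holds its plateau.")
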