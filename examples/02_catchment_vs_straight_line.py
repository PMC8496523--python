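"""Network catchment vs. the straight-line disc it is usually replaced by.

The 5 km straight-line disc overstates access: people cannot walk through
fields and rivers, only along the network. The network catchment is always
contained in the disc and usually much smaller.
"""

from microplan import (SynthConfig, build_catchment, generate_scene,
                       straight_line_catchment, zonal_population)

cfg = SynthConfig(seed=1)
network, grid, facilities = generate_scene(cfg)
fac = facilities[0]

net_cat = build_catchment(network, fac, cutoff_m=5000, buffer_m=50, max_snap_m=500)
disc_cat = straight_line_catchment(fac, cutoff_m=5000)

net_pop = zonal_population(grid, net_cat.polygon).population_total
disc_pop = zonal_population(grid, disc_cat.polygon).population_total

print(f"facility {fac.facility_id} at ({fac.x:.0f}, {fac.y:.0f})")
print(f"network catchment:  area {net_cat.polygon.area / 1e6:6.2f} km2, "
      f"population {net_pop:,}")
print(f"straight-line disc: area {disc_cat.polygon.area / 1e6:6.2f} km2, "
      f"population {disc_pop:,}")
print(f"disc overstates the served population {disc_pop / max(net_pop, 1):.1f}x")
# The ratio is the planning error a straight-line buffer would introduce.
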