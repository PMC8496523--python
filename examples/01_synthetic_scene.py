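"""Generate a synthetic study region and describe what it contains.

Builds a 10 x 10 km region: a settlement-clustered population raster at
100 m resolution stratified by age band and sex, a walking-connected road
network, and facilities placed where people live.
"""

from microplan import SynthConfig, generate_scene

cfg = SynthConfig(seed=1)  # defaults: 10 km extent, 5 settlements, 100 nodes
network, grid, facilities = generate_scene(cfg)

print(f"network: {len(network)} nodes, {network.n_edges} edges")
print(f"grid: {grid.nrows} x {grid.ncols} cells of {grid.cell_size_m:.0f} m, "
      f"{len(grid.strata)} age/sex strata")
print(f"total population: {grid.population:,}")
under5 = sum(int(grid.strata[k].sum()) for k in grid.strata
             if k.age_band in ("0", "1-4"))
print(f"children under 5: {under5:,}")
print(f"facilities: {[f.facility_id for f in facilities]}")
# The population total is a Poisson draw around the configured rate surface;
# under-5 counts come from the multinomial age/sex split of each cell.
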