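"""Grouped summary table, pooled row, and a campaign resource plan.

The summary mirrors the standard microplan reporting layout: per group the
facility count, total covered population, mean, sample SD, min and max.
Sub-group rows pool exactly into a combined row from (n, total, SD) alone.
"""

from microplan import (ResourceAssumptions, SynthConfig, build_all_catchments,
                       combine_group_summaries, compute_coverage,
                       estimate_resources, generate_scene, summarize_by_group)

cfg = SynthConfig(seed=1)
network, grid, facilities = generate_scene(cfg)
catchments, _ = build_all_catchments(network, facilities, 5000, buffer_m=50, max_snap_m=500)
coverage = compute_coverage(catchments, grid)

rows = summarize_by_group(coverage, {f.facility_id: f.group for f in facilities})
print(f"{'group':>10} {'N':>3} {'total':>8} {'mean':>7} {'sd':>6} {'min':>6} {'max':>6}")
for r in rows + [combine_group_summaries(rows)]:
    sd = "-" if r.sd_population is None else r.sd_population
    print(f"{r.group_label:>10} {r.n_facilities:>3} {r.population_total:>8,.0f} "
          f"{r.mean_population:>7,} {sd:>6} {r.min_population:>6,.0f} {r.max_population:>6,.0f}")

# a measles-style campaign for under-5s, one dose, 10-dose vials
assumptions = ResourceAssumptions(
    target_strata=(("0", "f"), ("0", "m"), ("1-4", "f"), ("1-4", "m")),
    doses_per_person=1.0, wastage_fraction=0.15, vial_doses=10,
    team_daily_throughput=150, campaign_days=5)
plan = estimate_resources(coverage, assumptions)
print(f"\ncampaign totals: target {plan.total_target:,} children, "
      f"{plan.total_doses:,} doses, {plan.total_vials:,} vials, {plan.total_teams} teams")
# Doses, vials and teams are per-facility ceilings summed over facilities.
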