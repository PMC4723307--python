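"""One season of the surrogate wheat model at each site archetype.

Generates synthetic weather from each site's climate statistics, applies the
site's soil and nitrogen management, and runs the reference cultivar from
sowing (15 May) to maturity.  The stress indices are seasonal means of the
daily water supply/demand deficit and of the nitrogen photosynthesis
limitation, on a 0 (none) to 1 (extreme) scale.
"""

from traitscreen import SITES, CropParameters, generate_weather, management_plan, run_crop

print(f"{'site':10s} {'flower':>6s} {'mature':>6s} {'LAI':>5s} {'biomass':>8s} "
      f"{'yield':>6s} {'protein':>7s} {'water':>6s} {'N':>5s}")
for name, site in SITES.items():
    weather = generate_weather(site, 3, seed=42)
    man = management_plan(site, sowing_tag="tpe", n_tag="tpe", co2=380.0)
    out = run_crop(CropParameters(), weather, site.soil(), man, start_year=2)
    print(f"{name:10s} {out.flowering_das:5d}d {out.maturity_das:5d}d "
          f"{out.lai_flowering:5.1f} {out.biomass:6.1f}t "
          f"{out.yield_t_ha:5.2f}t {out.grain_protein:6.1f}% "
          f"{out.water_stress_index:6.2f} {out.n_stress_index:5.2f}")

print("\ncolumns: days after sowing to flowering/maturity, LAI at flowering,"
      "\nbiomass and grain yield (t/ha), grain protein (%), seasonal water-"
      "\nand nitrogen-stress indices (0 none .. 1 extreme).")
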