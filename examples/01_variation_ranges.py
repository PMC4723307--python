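"""Variation ranges: how nominal trait values map to the screened intervals.

Every screened parameter varies over a band whose total width is 40% of the
nominal value for the reference cultivar: symmetric +/-20% where possible,
shifted one-sided when a hard bound (e.g. a fraction capped at 1) would be
crossed.
"""

from traitscreen import apply_range_rule, count_factors, packaged_registry

registry = packaged_registry()
print(f"packaged inventory: {len(registry)} parameters, "
      f"{len(registry.groups)} meta-parameter groups, "
      f"{count_factors(registry)} independent factors\n")

for name in ("vern_sens", "tt_end_of_juvenile", "photop_sens"):
    p = registry[name]
    rng = apply_range_rule(float(p.nominal), p.hard_lower, p.hard_upper)
    print(f"{name:22s} nominal {float(p.nominal):8.2f} {p.units:6s}"
          f" -> tested range [{rng.lower:g}, {rng.upper:g}]")

bounded = apply_range_rule(1.0, hard_upper=1.0)
print(f"\n{'fraction at cap':22s} nominal     1.00        "
      f"-> tested range [{bounded.lower:g}, {bounded.upper:g}] "
      f"(one-sided {bounded.one_sided}: the 40% width sits below the bound)")
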