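"""Packaged parameter inventory for the reference cultivar (Hartog).

The screen covers 103 candidate parameters: 62 single values and 41
function (curve) parameters.  Twenty of them — the traits named throughout
the analysis (phenology targets, photoperiod/vernalization sensitivities,
radiation use efficiency, extinction coefficient, specific leaf area,
transpiration efficiency, root water extractability, grain set and fill
traits, CO2 response modifiers, the leaf-expansion water-deficit threshold
and the senescence rate) — are *active*: the surrogate simulator consumes
them, so they carry true causal semantics.  The remaining 83 entries are
inert placeholders standing in for the long tail of model constants a full
crop model exposes; they are screened like every other factor and serve as
known-null controls.  Their names follow crop-model conventions but their
nominal values are synthetic.

Twenty placeholder parameters that could not vary independently in a real
model (paired minimum/critical/maximum nitrogen concentration curves, leaf
expansion geometry, root advance, temperature-senescence response, frost
thresholds) are tied into 7 meta-parameters, so the registry collapses to

    103 parameters - 20 grouped members + 7 groups = 90 independent factors.
"""

from __future__ import annotations

from importlib import resources

from .parameters import Curve, ParameterDef, Registry

__all__ = ["paper_registry", "desk_registry", "packaged_registry", "DESK_FACTORS"]


def _active() -> list[ParameterDef]:
    """The 20 simulator-consumed traits with Hartog nominal values."""
    P = ParameterDef
    return [
        P("tt_end_of_juvenile", "scalar", 555.0, "degCd", process="phenology", active=True),
        P("tt_floral_initiation", "scalar", 400.0, "degCd", process="phenology", active=True),
        P("tt_start_grain_fill", "scalar", 120.0, "degCd", process="phenology", active=True),
        P("photop_sens", "scalar", 3.0, "-", process="phenology", active=True),
        P("vern_sens", "scalar", 1.5, "-", process="phenology", active=True),
        P("transp_eff_cf", "scalar", 0.006, "kPa", process="water use", active=True),
        P("ll_modifier", "scalar", 1.0, "-", process="water uptake", active=True),
        P("grains_per_gram_stem", "scalar", 25.0, "grain/g", process="grain set", active=True),
        P("potential_grain_filling_rate", "scalar", 7.0e-5, "g/grain/degCd",
          process="grain filling", active=True),
        P("max_grain_size", "scalar", 0.041, "g", process="grain filling", active=True),
        P("co2_rue_modifier", "scalar", 0.25, "-", process="CO2 response", active=True),
        P("senescence_rate", "scalar", 0.0025, "/day", process="senescence", active=True),
        P("y_rue", "curve", Curve((1.0, 5.0, 10.0), (1.24, 1.24, 1.24)), "g/MJ",
          process="photosynthesis", active=True),
        P("y_extinct_coef", "curve", Curve((0.0, 1.0), (0.42, 0.42)), "-",
          process="light interception", active=True),
        P("y_sla", "curve", Curve((1.0, 6.0), (0.027, 0.020)), "m2/g",
          process="leaf expansion", active=True),
        P("y_frac_pod", "curve", Curve((5.0, 7.0), (0.30, 0.30)), "-",
          process="biomass partitioning", active=True),
        P("x_temp_grain_fill", "curve",
          Curve((0.0, 10.0, 15.0, 25.0, 35.0), (0.0, 0.5, 1.0, 1.0, 0.0)), "degC",
          scaling_mode="point", point_axis="x", point_index=1,
          process="grain filling", active=True),
        P("x_temp_grain_n_filling", "curve",
          Curve((0.0, 10.0, 15.0, 25.0, 40.0), (0.0, 0.6, 1.0, 1.0, 0.0)), "degC",
          scaling_mode="point", point_axis="x", point_index=2,
          process="grain N filling", active=True),
        P("y_co2_te_modifier", "curve", Curve((350.0, 700.0), (1.0, 1.37)), "-",
          scaling_mode="point", point_axis="y", point_index=1,
          process="CO2 response", active=True),
        P("x_sw_demand_ratio", "curve", Curve((0.1, 1.1), (0.0, 1.0)), "-",
          scaling_mode="point", point_axis="x", point_index=1,
          process="leaf expansion", active=True),
    ]


def _grouped_placeholders() -> list[ParameterDef]:
    """20 inert members tied into 7 meta-parameters (synthetic nominals)."""
    P, C = ParameterDef, Curve
    stage = (1.0, 4.0, 7.0)

    def nconc(organ: str, group: str, maxi: float, crit: float, mini: float):
        return [
            P(f"y_n_conc_max_{organ}", "curve", C(stage, (maxi, maxi * 0.7, maxi * 0.4)),
              "g/g", group=group, process=f"{organ} N demand"),
            P(f"y_n_conc_crit_{organ}", "curve", C(stage, (crit, crit * 0.7, crit * 0.4)),
              "g/g", group=group, process=f"{organ} N demand"),
            P(f"y_n_conc_min_{organ}", "curve", C(stage, (mini, mini * 0.7, mini * 0.4)),
              "g/g", group=group, process=f"{organ} N demand"),
        ]

    out: list[ParameterDef] = []
    out += nconc("leaf", "leaf_n_demand", 0.06, 0.045, 0.015)
    out += nconc("stem", "stem_n_demand", 0.04, 0.028, 0.008)
    out += nconc("pod", "pod_n_demand", 0.03, 0.02, 0.006)
    out += [
        P("x_node_no_leaf", "curve", C((1.0, 10.0, 25.0), (1.0, 10.0, 25.0)), "-",
          group="leaf_expansion_geom", process="leaf expansion"),
        P("y_leaf_size", "curve", C((1.0, 10.0, 25.0), (800.0, 2000.0, 2500.0)), "mm2",
          group="leaf_expansion_geom", process="leaf expansion"),
        P("node_no_correction", "scalar", 2.0, "-",
          group="leaf_expansion_geom", process="leaf expansion"),
        P("root_depth_rate", "curve", C(stage, (25.0, 20.0, 5.0)), "mm/day",
          group="root_advance", process="root growth"),
        P("x_sw_ratio_root", "curve", C((0.0, 0.25), (0.0, 0.25)), "-",
          group="root_advance", process="root growth"),
        P("y_sw_fac_root", "curve", C((0.0, 0.25), (0.2, 1.0)), "-",
          group="root_advance", process="root growth"),
        P("x_temp_senescence", "curve", C((-10.0, 0.0, 5.0), (-10.0, 0.0, 5.0)), "degC",
          group="temp_senescence", process="senescence"),
        P("y_senescence_fac_temp", "curve", C((-10.0, 0.0, 5.0), (1.0, 0.5, 0.0)), "-",
          group="temp_senescence", process="senescence"),
        P("sen_light_time_const", "scalar", 10.0, "day",
          group="temp_senescence", process="senescence"),
        P("frost_temp_low", "scalar", -5.0, "degC",
          group="frost_response", process="frost response"),
        P("frost_fraction_low", "scalar", 0.9, "-", hard_upper=1.0, hard_lower=0.0,
          group="frost_response", process="frost response"),
    ]
    return out


def _ungrouped_placeholder_curves() -> list[ParameterDef]:
    """17 inert, ungrouped function parameters."""
    P, C = ParameterDef, Curve
    specs = [
        ("x_temp", C((0.0, 26.0, 34.0), (0.0, 26.0, 0.0)), "degC", "thermal time"),
        ("y_tiller_tt", C((1.0, 4.0), (200.0, 600.0)), "degCd", "tillering"),
        ("x_vernal_temp", C((-5.0, 2.0, 15.0), (-5.0, 2.0, 15.0)), "degC", "vernalization"),
        ("y_vernal_days", C((-5.0, 2.0, 15.0), (0.0, 1.0, 0.0)), "-", "vernalization"),
        ("y_leaf_no_frac", C((1.0, 25.0), (0.7, 1.0)), "-", "leaf appearance"),
        ("x_lai_ratio", C((0.0, 0.5), (0.0, 0.5)), "-", "tillering"),
        ("y_leaf_no_dead", C((1.0, 7.0), (0.0, 0.6)), "-", "senescence"),
        ("x_ave_temp_photo", C((0.0, 15.0, 35.0), (0.0, 15.0, 35.0)), "degC", "photosynthesis"),
        ("y_stress_photo", C((0.0, 15.0, 35.0), (0.3, 1.0, 0.2)), "-", "photosynthesis"),
        ("x_ws_root", C((0.0, 1.0), (0.0, 1.0)), "-", "root growth"),
        ("y_ws_root_fac", C((0.0, 1.0), (0.3, 1.0)), "-", "root growth"),
        ("y_frac_leaf_pre_flower", C((1.0, 5.0), (0.55, 0.1)), "-", "partitioning"),
        ("y_ratio_root_shoot", C((1.0, 5.0), (1.0, 0.1)), "-", "partitioning"),
        ("x_stage_no_partition", C((1.0, 11.0), (1.0, 11.0)), "-", "partitioning"),
        ("y_height_stem_wt", C((0.0, 1000.0), (0.0, 600.0)), "mm", "canopy"),
        ("x_row_spacing", C((200.0, 800.0), (200.0, 800.0)), "mm", "canopy"),
        ("y_extinct_coef_row", C((200.0, 800.0), (0.48, 0.32)), "-", "canopy"),
    ]
    return [P(n, "curve", c, u, process=pr) for n, c, u, pr in specs]


def _ungrouped_placeholder_scalars() -> list[ParameterDef]:
    """46 inert, ungrouped single-value parameters."""
    P = ParameterDef
    specs = [
        ("tt_emerg_limit", 300.0, "degCd", "emergence"),
        ("shoot_lag", 40.0, "degCd", "emergence"),
        ("shoot_rate", 1.5, "degCd/mm", "emergence"),
        ("initial_root_depth", 100.0, "mm", "root growth"),
        ("leaf_app_rate1", 95.0, "degCd", "leaf appearance"),
        ("leaf_app_rate2", 130.0, "degCd", "leaf appearance"),
        ("leaf_init_rate", 50.0, "degCd", "leaf appearance"),
        ("min_tpla", 200.0, "mm2", "leaf expansion"),
        ("initial_tpla", 200.0, "mm2", "leaf expansion"),
        ("tiller_curve", 1.5, "-", "tillering"),
        ("tiller_tt_infl", 500.0, "degCd", "tillering"),
        ("dm_tiller_max", 2.0, "g", "tillering"),
        ("skip_row_factor", 1.0, "-", "canopy"),
        ("pesw_germ", 0.05, "mm/mm", "emergence"),
        ("grain_n_conc_min", 0.012, "g/g", "grain N filling"),
        ("n_fact_photo", 1.5, "-", "N stress"),
        ("n_fact_pheno", 5.8, "-", "N stress"),
        ("n_fact_expansion", 0.6, "-", "N stress"),
        ("n_uptake_max", 0.6, "g/m2/day", "N uptake"),
        ("no3_diffn_const", 2.0, "-", "N uptake"),
        ("root_extinction", 3.0, "-", "root growth"),
        ("specific_root_length", 105000.0, "mm/g", "root growth"),
        ("transp_eff_cf_pre", 0.005, "kPa", "water use"),
        ("eo_crop_factor", 1.5, "-", "water demand"),
        ("svp_fract", 0.75, "-", "water demand"),
        ("minsw", 0.5, "mm", "water uptake"),
        ("grain_water_content", 0.125, "g/g", "grain filling"),
        ("dead_detach_frac", 0.003, "/day", "senescence"),
        ("sen_detach_frac", 0.002, "/day", "senescence"),
        ("sen_rate_water", 0.1, "-", "senescence"),
        ("sen_threshold_heat", 34.0, "degC", "senescence"),
        ("spike_no_per_plant", 2.5, "-", "grain set"),
        ("head_grain_no_max", 60.0, "grain", "grain set"),
        ("seed_wt_min", 0.01, "g", "grain set"),
        ("grain_growth_period", 580.0, "degCd", "grain filling"),
        ("phase_tt_emerg_to_endjuv_min", 400.0, "degCd", "phenology"),
        ("tt_maturity_to_ripe", 1.0, "degCd", "phenology"),
        ("tt_ripe_limit", 500.0, "degCd", "phenology"),
        ("photoperiod_base", 8.0, "h", "phenology"),
        ("photoperiod_optimum", 20.0, "h", "phenology"),
        ("twilight_angle", -2.2, "degree", "phenology"),
        ("vern_base_temp", 2.0, "degC", "vernalization"),
        ("amp_to_dev_fact", 0.5, "-", "thermal time"),
        ("root_advance_wet", 30.0, "mm/day", "root growth"),
        ("kl_factor_sub", 0.8, "-", "water uptake"),
        ("crit_cover_for_es", 0.85, "-", "soil evaporation"),
    ]
    return [P(n, "scalar", v, u, process=pr) for n, v, u, pr in specs]


def paper_registry() -> Registry:
    """The full 103-parameter inventory (62 scalars, 41 curves, 7 groups)."""
    return Registry(_active() + _grouped_placeholders()
                    + _ungrouped_placeholder_curves()
                    + _ungrouped_placeholder_scalars())


# Desk-scale factor set: 16 active traits + 4 inert controls = 20 factors,
# small enough for an end-to-end screen on one CPU in minutes.
DESK_FACTORS = [
    "tt_end_of_juvenile", "tt_floral_initiation", "tt_start_grain_fill",
    "photop_sens", "vern_sens", "transp_eff_cf", "ll_modifier",
    "grains_per_gram_stem", "potential_grain_filling_rate", "max_grain_size",
    "y_rue", "y_extinct_coef", "y_sla", "y_frac_pod", "x_temp_grain_fill",
    "y_co2_te_modifier",
    # inert controls
    "tt_emerg_limit", "x_temp", "shoot_lag", "min_tpla",
]


def desk_registry() -> Registry:
    """Reduced 20-factor registry for desk-scale end-to-end runs."""
    return paper_registry().subset(DESK_FACTORS)


def packaged_registry() -> Registry:
    """Load the shipped registry table (identical to :func:`paper_registry`)."""
    from .parameters import load_registry

    ref = resources.files("traitscreen") / "data" / "hartog_registry.csv"
    with resources.as_file(ref) as path:
        return load_registry(path)
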