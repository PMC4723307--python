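name,kind,nominal,units,hard_lower,hard_upper,scaling_mode,point_axis,point_index,group,process,active
tt_end_of_juvenile,scalar,555.0,degCd,,,full,,,,phenology,1
tt_floral_initiation,scalar,400.0,degCd,,,full,,,,phenology,1
tt_start_grain_fill,scalar,120.0,degCd,,,full,,,,phenology,1
photop_sens,scalar,3.0,-,,,full,,,,phenology,1
vern_sens,scalar,1.5,-,,,full,,,,phenology,1
transp_eff_cf,scalar,0.006,kPa,,,full,,,,water use,1
ll_modifier,scalar,1.0,-,,,full,,,,water uptake,1
grains_per_gram_stem,scalar,25.0,grain/g,,,full,,,,grain set,1
potential_grain_filling_rate,scalar,7e-05,g/grain/degCd,,,full,,,,grain filling,1
max_grain_size,scalar,0.041,g,,,full,,,,grain filling,1
co2_rue_modifier,scalar,0.25,-,,,full,,,,CO2 response,1
senescence_rate,scalar,0.0025,/day,,,full,,,,senescence,1
y_rue,curve,1.0;5.0;10.0|1.24;1.24;1.24,g/MJ,,,full,,,,photosynthesis,1
y_extinct_coef,curve,0.0;1.0|0.42;0.42,-,,,full,,,,light interception,1
y_sla,curve,1.0;6.0|0.027;0.02,m2/g,,,full,,,,leaf expansion,1
y_frac_pod,curve,5.0;7.0|0.3;0.3,-,,,full,,,,biomass partitioning,1
x_temp_grain_fill,curve,0.0;10.0;15.0;25.0;35.0|0.0;0.5;1.0;1.0;0.0,degC,,,point,x,1,,grain filling,1
x_temp_grain_n_filling,curve,0.0;10.0;15.0;25.0;40.0|0.0;0.6;1.0;1.0;0.0,degC,,,point,x,2,,grain N filling,1
y_co2_te_modifier,curve,350.0;700.0|1.0;1.37,-,,,point,y,1,,CO2 response,1
x_sw_demand_ratio,curve,0.1;1.1|0.0;1.0,-,,,point,x,1,,leaf expansion,1
y_n_conc_max_leaf,curve,1.0;4.0;7.0|0.06;0.041999999999999996;0.024,g/g,,,full,,,leaf_n_demand,leaf N demand,0
y_n_conc_crit_leaf,curve,1.0;4.0;7.0|0.045;0.0315;0.018,g/g,,,full,,,leaf_n_demand,leaf N demand,0
y_n_conc_min_leaf,curve,1.0;4.0;7.0|0.015;0.010499999999999999;0.006,g/g,,,full,,,leaf_n_demand,leaf N demand,0
y_n_conc_max_stem,curve,1.0;4.0;7.0|0.04;0.027999999999999997;0.016,g/g,,,full,,,stem_n_demand,stem N demand,0
y_n_conc_crit_stem,curve,1.0;4.0;7.0|0.028;0.0196;0.011200000000000002,g/g,,,full,,,stem_n_demand,stem N demand,0
y_n_conc_min_stem,curve,1.0;4.0;7.0|0.008;0.0056;0.0032,g/g,,,full,,,stem_n_demand,stem N demand,0
y_n_conc_max_pod,curve,1.0;4.0;7.0|0.03;0.020999999999999998;0.012,g/g,,,full,,,pod_n_demand,pod N demand,0
y_n_conc_crit_pod,curve,1.0;4.0;7.0|0.02;0.013999999999999999;0.008,g/g,,,full,,,pod_n_demand,pod N demand,0
y_n_conc_min_pod,curve,1.0;4.0;7.0|0.006;0.0042;0.0024000000000000002,g/g,,,full,,,pod_n_demand,pod N demand,0
x_node_no_leaf,curve,1.0;10.0;25.0|1.0;10.0;25.0,-,,,full,,,leaf_expansion_geom,leaf expansion,0
y_leaf_size,curve,1.0;10.0;25.0|800.0;2000.0;2500.0,mm2,,,full,,,leaf_expansion_geom,leaf expansion,0
node_no_correction,scalar,2.0,-,,,full,,,leaf_expansion_geom,leaf expansion,0
root_depth_rate,curve,1.0;4.0;7.0|25.0;20.0;5.0,mm/day,,,full,,,root_advance,root growth,0
x_sw_ratio_root,curve,0.0;0.25|0.0;0.25,-,,,full,,,root_advance,root growth,0
y_sw_fac_root,curve,0.0;0.25|0.2;1.0,-,,,full,,,root_advance,root growth,0
x_temp_senescence,curve,-10.0;0.0;5.0|-10.0;0.0;5.0,degC,,,full,,,temp_senescence,senescence,0
y_senescence_fac_temp,curve,-10.0;0.0;5.0|1.0;0.5;0.0,-,,,full,,,temp_senescence,senescence,0
sen_light_time_const,scalar,10.0,day,,,full,,,temp_senescence,senescence,0
frost_temp_low,scalar,-5.0,degC,,,full,,,frost_response,frost response,0
frost_fraction_low,scalar,0.9,-,0.0,1.0,full,,,frost_response,frost response,0
x_temp,curve,0.0;26.0;34.0|0.0;26.0;0.0,degC,,,full,,,,thermal time,0
y_tiller_tt,curve,1.0;4.0|200.0;600.0,degCd,,,full,,,,tillering,0
x_vernal_temp,curve,-5.0;2.0;15.0|-5.0;2.0;15.0,degC,,,full,,,,vernalization,0
y_vernal_days,curve,-5.0;2.0;15.0|0.0;1.0;0.0,-,,,full,,,,vernalization,0
y_leaf_no_frac,curve,1.0;25.0|0.7;1.0,-,,,full,,,,leaf appearance,0
x_lai_ratio,curve,0.0;0.5|0.0;0.5,-,,,full,,,,tillering,0
y_leaf_no_dead,curve,1.0;7.0|0.0;0.6,-,,,full,,,,senescence,0
x_ave_temp_photo,curve,0.0;15.0;35.0|0.0;15.0;35.0,degC,,,full,,,,photosynthesis,0
y_stress_photo,curve,0.0;15.0;35.0|0.3;1.0;0.2,-,,,full,,,,photosynthesis,0
x_ws_root,curve,0.0;1.0|0.0;1.0,-,,,full,,,,root growth,0
y_ws_root_fac,curve,0.0;1.0|0.3;1.0,-,,,full,,,,root growth,0
y_frac_leaf_pre_flower,curve,1.0;5.0|0.55;0.1,-,,,full,,,,partitioning,0
y_ratio_root_shoot,curve,1.0;5.0|1.0;0.1,-,,,full,,,,partitioning,0
x_stage_no_partition,curve,1.0;11.0|1.0;11.0,-,,,full,,,,partitioning,0
y_height_stem_wt,curve,0.0;1000.0|0.0;600.0,mm,,,full,,,,canopy,0
x_row_spacing,curve,200.0;800.0|200.0;800.0,mm,,,full,,,,canopy,0
y_extinct_coef_row,curve,200.0;800.0|0.48;0.32,-,,,full,,,,canopy,0
tt_emerg_limit,scalar,300.0,degCd,,,full,,,,emergence,0
shoot_lag,scalar,40.0,degCd,,,full,,,,emergence,0
shoot_rate,scalar,1.5,degCd/mm,,,full,,,,emergence,0
initial_root_depth,scalar,100.0,mm,,,full,,,,root growth,0
leaf_app_rate1,scalar,95.0,degCd,,,full,,,,leaf appearance,0
leaf_app_rate2,scalar,130.0,degCd,,,full,,,,leaf appearance,0
leaf_init_rate,scalar,50.0,degCd,,,full,,,,leaf appearance,0
min_tpla,scalar,200.0,mm2,,,full,,,,leaf expansion,0
initial_tpla,scalar,200.0,mm2,,,full,,,,leaf expansion,0
tiller_curve,scalar,1.5,-,,,full,,,,tillering,0
tiller_tt_infl,scalar,500.0,degCd,,,full,,,,tillering,0
dm_tiller_max,scalar,2.0,g,,,full,,,,tillering,0
skip_row_factor,scalar,1.0,-,,,full,,,,canopy,0
pesw_germ,scalar,0.05,mm/mm,,,full,,,,emergence,0
grain_n_conc_min,scalar,0.012,g/g,,,full,,,,grain N filling,0
n_fact_photo,scalar,1.5,-,,,full,,,,N stress,0
n_fact_pheno,scalar,5.8,-,,,full,,,,N stress,0
n_fact_expansion,scalar,0.6,-,,,full,,,,N stress,0
n_uptake_max,scalar,0.6,g/m2/day,,,full,,,,N uptake,0
no3_diffn_const,scalar,2.0,-,,,full,,,,N uptake,0
root_extinction,scalar,3.0,-,,,full,,,,root growth,0
specific_root_length,scalar,105000.0,mm/g,,,full,,,,root growth,0
transp_eff_cf_pre,scalar,0.005,kPa,,,full,,,,water use,0
eo_crop_factor,scalar,1.5,-,,,full,,,,water demand,0
svp_fract,scalar,0.75,-,,,full,,,,water demand,0
minsw,scalar,0.5,mm,,,full,,,,water uptake,0
grain_water_content,scalar,0.125,g/g,,,full,,,,grain filling,0
dead_detach_frac,scalar,0.003,/day,,,full,,,,senescence,0
sen_detach_frac,scalar,0.002,/day,,,full,,,,senescence,0
sen_rate_water,scalar,0.1,-,,,full,,,,senescence,0
sen_threshold_heat,scalar,34.0,degC,,,full,,,,senescence,0
spike_no_per_plant,scalar,2.5,-,,,full,,,,grain set,0
head_grain_no_max,scalar,60.0,grain,,,full,,,,grain set,0
seed_wt_min,scalar,0.01,g,,,full,,,,grain set,0
grain_growth_period,scalar,580.0,degCd,,,full,,,,grain filling,0
phase_tt_emerg_to_endjuv_min,scalar,400.0,degCd,,,full,,,,phenology,0
tt_maturity_to_ripe,scalar,1.0,degCd,,,full,,,,phenology,0
tt_ripe_limit,scalar,500.0,degCd,,,full,,,,phenology,0
photoperiod_base,scalar,8.0,h,,,full,,,,phenology,0
photoperiod_optimum,scalar,20.0,h,,,full,,,,phenology,0
twilight_angle,scalar,-2.2,degree,,,full,,,,phenology,0
vern_base_temp,scalar,2.0,degC,,,full,,,,vernalization,0
amp_to_dev_fact,scalar,0.5,-,,,full,,,,thermal time,0
root_advance_wet,scalar,30.0,mm/day,,,full,,,,root growth,0
kl_factor_sub,scalar,0.8,-,,,full,,,,water uptake,0
crit_cover_for_es,scalar,0.85,-,,,full,,,,soil evaporation,0
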