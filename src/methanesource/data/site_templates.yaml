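# Synthetic site archetypes emulating three styles of sill-driven thermal
# alteration of an organic-rich marine sediment column.
#
#   no_sill          — cool reference column, shallow SMTZ, modest methane
#   deep_cooled_sill — deep, thermally re-equilibrated sill; SMTZ twice as
#                      deep; two methane peaks with the middle one largest
#   shallow_hot_sill — young, shallow sill; steep geothermal gradient;
#                      deepest SMTZ; large, deep methane peaks
#
# smtz_depth: mbsf. thermal_gradient: degC/km. methane_peaks: [depth_mbsf,
# peak mM]. sulfate_surface: mM. pmm_at_smtz / pmm_at_bottom: ground-truth
# microbial methane fraction used by the forward mixing simulator, declining
# linearly with depth through the methanogenic zone.
no_sill:
  smtz_depth: 45.0
  thermal_gradient: 220.0
  sill_depth: null
  methane_peaks: [[80.0, 1.2], [180.0, 0.8]]
  sulfate_surface: 28.0
  max_depth: 295.0
  surface_T: 3.0
  water_depth: 1600.0
  pmm_at_smtz: 0.75
  pmm_at_bottom: 0.25
deep_cooled_sill:
  smtz_depth: 80.0
  thermal_gradient: 230.0
  sill_depth: 350.0
  methane_peaks: [[110.0, 2.5], [225.0, 6.0]]
  sulfate_surface: 28.0
  max_depth: 340.0
  surface_T: 3.0
  water_depth: 1600.0
  pmm_at_smtz: 1.0
  pmm_at_bottom: 0.45
shallow_hot_sill:
  smtz_depth: 100.0
  thermal_gradient: 700.0
  sill_depth: 130.0
  methane_peaks: [[115.0, 2.5], [160.0, 12.0]]
  sulfate_surface: 28.0
  max_depth: 200.0
  surface_T: 3.0
  water_depth: 1800.0
  pmm_at_smtz: 0.55
  pmm_at_bottom: 0.1
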