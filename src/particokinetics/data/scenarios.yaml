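# Built-in scenario parameters (lab units; converted to SI at load).
# Shared simulation conditions: 310 K, media density 1.0 g/mL, media
# viscosity 0.69 mPa.s (0.74 mPa.s for the serum-containing silica study).

materials:
  polystyrene: {density_g_cm3: 1.05}
  silica: {density_g_cm3: 2.2}
  titanium_dioxide: {density_g_cm3: 4.23}
  iron_oxide: {density_g_cm3: 5.2}
  gold: {density_g_cm3: 19.32}

default_medium:
  temperature_K: 310.0
  viscosity_mPa_s: 0.69
  density_g_mL: 1.0

polystyrene_table1:
  diameters_nm: [24, 100, 210, 500, 1100]
  material: polystyrene
  concentration_particles_per_mL: 3.7e+8
  media_height_cm: 0.31
  counting_area_cm2: 3.717e-5
  duration_s: 500.0
  # transport-rate comparison, particles per 500 s over the counting field;
  # observed values are the microscopy counts (two runs where given)
  expected_counts:
    simulated: {24: 181, 100: 89, 210: 63, 500: 73, 1100: 62}
    observed: {24: [190], 100: [196, 155], 210: [101, 140], 500: [96, 130], 1100: [140, 200]}
  # the 500 and 1100 nm simulated counts exceed the independent
  # first-passage oracle (~44 and ~47); see docs/methods.md
  oracle_consistent_nm: [24, 100, 210]

silica_lison:
  hydrodynamic_diameter_nm: 34.8
  tem_diameter_nm: 29.3
  material: silica
  viscosity_mPa_s: 0.74   # serum-containing DMEM
  well_area_cm2: 0.81
  media_heights_mm: [1.1, 2.2, 3.3, 4.4, 4.5]
  duration_h: 6.0
  constant_concentration_ug_mL: 37.0
  constant_mass_ug: 16.7

iron_oxide_agglomerates:
  monomer_diameter_nm: 34.8
  material: iron_oxide
  packing_factor: 0.637
  fractal_dimensions: [2.0, 2.1, 2.2, 2.3, 2.4]
  best_fractal_dimension: 2.3
  agglomerate_mean_nm: 993.7
  agglomerate_sd_nm: 272.1
  n_classes: 5
  distribution_seed: 7
  media_height_mm: 1.06
  concentration_ug_mL: 2.0
  media_volume_mL: 3.0
  duration_h: 8.0

generalization:
  concentration_ug_mL: 10.0
  media_volume_mL: 3.0
  media_height_mm: 3.1
  duration_h: 24.0
  sweep_diameters_nm: [10, 30, 100, 300, 1000, 3000]
  height_sweep_mm: [1.0, 2.0, 3.1, 5.0, 10.0]
  height_sweep_material: titanium_dioxide
  height_sweep_diameters_nm: [10, 50, 100, 500]
  agglomeration_monomer_nm: 34.6
  agglomeration_material: iron_oxide
  agglomeration_counts: [1, 10, 100, 1000, 10000]
  agglomeration_fractal_dimensions: [2.2, 2.4]
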