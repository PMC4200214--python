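# Default pipeline configuration: carboxylated SPIO (magnetite) nanoparticles,
# RPMI + serum culture medium, Balb/c mouse inhalation study conditions and the
# occupational-limit human scenario.  All values are bench units (nm, g/cm3,
# Pa.s, K, mg/m3, ml, mm, h).
seed: 0

particle:
  diameter_nm: 13.0          # TEM primary diameter
  density_g_cm3: 5.2         # magnetite bulk density

agglomerate:
  hydrodynamic_diameter_nm: 276.0   # DLS size in culture medium
  fractal_dimension: 2.1
  packing_factor: 0.637

medium:
  density_g_cm3: 1.0
  viscosity_pa_s: 0.00074    # serum-supplemented medium
  temperature_k: 310.0

geometry:
  media_height_mm: 2.6
  media_volume_ml: 2.5

aerosol:
  cmd_nm: 68.6
  gsd: 1.65
  mass_concentration_mg_m3: 19.9
  effective_density_g_cm3: 5.0   # density used for count-to-mass conversion

invitro:
  nominal_concentration_ug_ml: 50.0
  times_h: [1.0, 2.0, 4.0, 8.0, 24.0]
  n_cells: 250000.0          # epithelial cells seeded per well
  well_area_cm2: 9.6         # 6-well plate well
  true_fractions: [0.93, 0.93, 0.89, 0.67, 0.68]  # synthetic-data ground truth
  association_covariate: delivered   # or "time"

physiology_mouse:            # measured during exposure; used for inhaled mass
  tidal_volume_ml: 0.24
  respiratory_rate_per_min: 371.0
  minute_volume_ml_min: 77.0

physiology_mouse_deposition_model:  # resting values a deposition model assumes
  tidal_volume_ml: 0.24
  respiratory_rate_per_min: 317.0

physiology_human:            # reference worker, light work
  tidal_volume_ml: 1250.0
  respiratory_rate_per_min: 16.0
  minute_volume_ml_min: 20000.0

scenario_mouse:
  mass_concentration_mg_m3: 19.9
  duration_h: 4.0
  label: mouse_inhalation

occupational_limit:
  limit_value_mg_m3: 10.0    # PEL for iron oxide dust and fume, as Fe
  basis: as_Fe
  duration_h: 8.0

iron_oxide_species: Fe3O4

deposition:
  regional_split: [0.028, 0.34, 0.62]
  total_deposited_ug: 14.5   # measured total lung burden at end of exposure
  total_macrophages_mouse: 1.25e6
  total_macrophages_human: 2.0e9      # synthetic human fixture value
  scavenging_fraction: 1.0
  human_deposition_efficiency: 0.30   # synthetic human fixture: deposited/inhaled
  enhancement_factor: 65.0   # bifurcation hot-spot, 100 um patch, ~200 nm particles

clearance:
  m0_ug: 14.5
  rate_ug_per_h: 0.052       # 8.6 %/day of the deposited 14.5 ug
  times_h: [0.0, 6.0, 24.0, 48.0, 96.0, 168.0]

noise:
  retention_rel_sd: 0.05
  invitro_rel_sd: 0.02
  mpd_rel_sd: 0.05

# Effect / exposure dose bands for the cross-system comparison
bands:
  - {system: in_vitro, metric: per_cell, lower: 8.0, upper: 35.0, cell_context: BMM, effect_observed: "yes"}
  - {system: in_vivo, metric: per_cell, lower: 1.0, upper: 100.0, cell_context: alveolar_macrophage, effect_observed: "yes"}
  - {system: in_vitro, metric: per_area, lower: 1.2, upper: 4.0, cell_context: C10_epithelial, effect_observed: "yes"}
  - {system: in_vivo, metric: per_area, lower: 0.009, upper: 0.13, cell_context: alveolar_tissue, effect_observed: "yes"}
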