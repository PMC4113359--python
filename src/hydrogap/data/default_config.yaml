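# Default run configuration: young-secondary succession protocol under the
# current climate of the north Chiloe study site (weather-station records
# 1998-2009).  Every physical constant is visible here and overridable.

protocol: YS          # YS: bare ground, 60 yr | OG: inventory, 1000 yr | custom
seed: 0
replicates: 1
grid: [5, 5]          # 25 patches of 20x20 m = 1 ha
s0: 0.5               # initial normalized soil moisture

species_file: species_demo.tsv      # illustrative demo parameterization
# inventory_file: inventory_demo.tsv  # required for the OG protocol

climate:
  DJF: {mean_interval: 0.90, mean_event_depth: 8.3, prescribed_rain: 284.6,
        temp_mu: 12.5, temp_sigma: 2.6,
        rg_mu_dry: 1413.9, rg_sigma_dry: 317.0,
        rg_mu_wet: 986.9, rg_sigma_wet: 378.2}
  MAM: {mean_interval: 0.55, mean_event_depth: 12.8, prescribed_rain: 543.6,
        temp_mu: 10.1, temp_sigma: 3.6,
        rg_mu_dry: 701.2, rg_sigma_dry: 294.1,
        rg_mu_wet: 398.8, rg_sigma_wet: 261.6}
  JJA: {mean_interval: 0.29, mean_event_depth: 16.0, prescribed_rain: 813.4,
        temp_mu: 8.4, temp_sigma: 4.4,
        rg_mu_dry: 408.9, rg_sigma_dry: 159.1,
        rg_mu_wet: 229.7, rg_sigma_wet: 139.4}
  SON: {mean_interval: 0.54, mean_event_depth: 9.5, prescribed_rain: 424.5,
        temp_mu: 9.8, temp_sigma: 3.3,
        rg_mu_dry: 1065.5, rg_sigma_dry: 348.7,
        rg_mu_wet: 640.8, rg_sigma_wet: 320.1}

soil:
  porosity_n: 0.757          # vertically averaged porosity
  depth_z: 520.0             # rooting depth, mm (bucket capacity n*z)
  k_sat: 4.0                 # saturated hydraulic conductivity, mm/day
  theta_wp: 0.125            # wilting point (normalized s)
  theta_fc: 0.3              # field capacity (normalized s)
  msw_fraction: 1.0          # theta_msw = wp + fraction*(fc - wp)
  drainage_exponent: 2.0     # percolation power law Q = k_sat * s^c
  thresholds_volumetric: false

canopy:
  alpha_h: 0.7               # initial slope of the interception curve
  f_h: 3.0                   # storage-curve shape, mm/day
  lai_max: 5.5               # maximum LAI of the forest
  wue: 9.0                   # water-use efficiency, g CO2 / kg H2O
  anchor_lai: 5.0            # calibration anchor: S(5.0) = 4.9 mm
  anchor_storage_mm: 4.9

constants:
  latitude_deg: -41.85
  gamma: 65.0                # psychrometric constant, Pa/K
  latent_heat: 2.56e+6       # J/kg
  pt_alpha: 1.041            # Priestley-Taylor coefficient (calibrated)
  albedo: 0.17
  par_energy_j_per_umol: 0.2174
  par_fraction: 0.5
  rg_clear_sky: 1800.0       # umol m-2 s-1 (sunshine-fraction scale)
  lw_a: 107.0                # net-longwave coefficient, W m-2
  lw_b: 0.2                  # cloudless fraction weight
  active_days: 365           # active photosynthetic period (evergreen)

# scenario:                  # uncomment for drought/warming forcing
#   eta_factor: 0.5
#   lambda_factor: 1.5
#   warming: false
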