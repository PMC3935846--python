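# Example qsdm pipeline configuration (desk-scale).
#
# With no observation/raster paths the simulate stage generates synthetic
# inputs; point `observations` at a CSV (sample_id,velocity,inundation,
# biomass) and `velocity_raster`/`inundation_raster` at ESRI ASCII grids
# to run on real data.  Omitted keys use the production defaults
# (tau grid 0.01-0.99 step 0.02, tau_upper 0.975, n_iter 5000,
# n_classes 10, n_sim 5).

seed: 1
output_dir: qsdm_out

synthetic:
  n_obs: 2000
  shape: [60, 80]

formula: [velocity, inundation, interaction]

tau_min: 0.01
tau_max: 0.99
tau_step: 0.02
tau_upper: 0.975

# reduced from the production default of 5000 to keep the example quick
n_iter: 200
n_classes: 10
class_scheme: frequency
validation_taus: [0.175, 0.375, 0.575, 0.775]

n_sim: 5
occurrence_basis: sampled
tau_sampling: continuous
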