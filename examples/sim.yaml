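# Configuration for `pdmap simulate --config examples/sim.yaml --out sim/`
# A compact four-layer root: epidermis/cortex/endodermis rings of six cells
# around a single-cell vascular core.  All lengths in μm.
geometry:
  layer_radii: [12.0, 8.0, 4.5, 2.2]
  cells_per_ring: [6, 6, 6, 1]
  axial_cell_length: [11.0, 11.0, 11.0, 11.0]
  stack_extent: [28.0, 28.0, 44.0]
  voxel_size: [0.25, 0.25, 0.25]
  layer_names: [epidermis, cortex, endodermis, core]

pit_fields:
  # expected spots per μm² of wall, by wall orientation class
  rate_per_area:
    apical_basal: 0.08
    radial: 0.02
    circumferential: 0.02
  cluster_mode: uniform      # or "thomas" for clustered pit fields
  offspring_per_parent: 10.0
  cluster_sigma: 1.2
  spot_sigma_psf: 0.2
  spot_amplitude: 1.0
  noise_sd: 0.02

wall:
  thickness: 1.0
  blur_sigma: 0.2
  noise_sd: 0.0
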