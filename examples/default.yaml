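# Default synthetic study conditions: 200 x 200 km landscape at 1 km cells.
# Screening thresholds follow standard published practice; resistance
# weights and carbon densities are documented placeholders.
seed: 1
shape: [200, 200]
cell_size: 1000.0
clumping: 4.0
n_source_blobs: 12
foreground: [2, 3, 4]      # forest, grassland, water
edge_width: 1
min_area_km2: 25.0
dpc_threshold: 0.5
distance_threshold_m: 2500.0
prob_at_threshold: 0.5
grades: 5
buffers_m: [500, 1000, 1500, 2000]
attack_mode: malicious
attack_fraction: 1.0
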