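# Brain-tumour-MRI-like phantom preset: 4 channels (pseudo-modalities),
# 4 classes with three strictly nested foreground shells painted
# outside-in.  Intensities are on a z-score-like scale (background ~0).
grid: [64, 64, 64]
channels: 4
num_classes: 4
noise_sigma: 0.1
blur_sigma: 0.5
spacing: [1.0, 1.0, 1.0]
center_jitter: 0.04
organs:
  - {class_id: 1, shape: ellipsoid, center: [0.5, 0.5, 0.5], radii: [0.34, 0.31, 0.32]}
  - {class_id: 2, shape: ellipsoid, center: [0.5, 0.5, 0.5], radii: [0.21, 0.19, 0.20]}
  - {class_id: 3, shape: ellipsoid, center: [0.5, 0.5, 0.5], radii: [0.10, 0.09, 0.10]}
intensity_table:
  - [0.0, 0.0, 0.0, 0.0]
  - [1.5, 0.5, -0.5, 1.0]
  - [0.5, 1.5, 1.0, -0.5]
  - [-0.5, 1.0, 1.8, 1.5]
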