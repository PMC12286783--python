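# Reduced abdominal-like preset for desk-scale experiments: 48^3 grid,
# one channel, two foreground structures (3 classes including background).
grid: [48, 48, 48]
channels: 1
num_classes: 3
noise_sigma: 8.0
blur_sigma: 0.5
spacing: [1.0, 1.0, 1.0]
center_jitter: 0.05
organs:
  - {class_id: 1, shape: blob,      center: [0.40, 0.60, 0.50], radii: [0.22, 0.20, 0.19]}
  - {class_id: 2, shape: ellipsoid, center: [0.65, 0.30, 0.45], radii: [0.12, 0.10, 0.13]}
intensity_table:
  - [0.0]
  - [120.0]
  - [240.0]
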