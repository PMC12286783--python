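# Abdominal-CT-like phantom preset: 1 channel, 14 classes (13 foreground
# structures mixing large and small shapes).  Intensities are CT-like
# arbitrary units with >= 35-unit inter-class gaps; noise_sigma is kept
# below gap/4 so the phantom is learnable by construction.
grid: [64, 64, 64]
channels: 1
num_classes: 14
noise_sigma: 8.0
blur_sigma: 0.7
spacing: [1.0, 1.0, 1.0]
center_jitter: 0.03
organs:
  # large structures first; later (small) entries overwrite earlier ones
  - {class_id: 6,  shape: blob,      center: [0.38, 0.68, 0.55], radii: [0.19, 0.17, 0.16]}   # liver-like
  - {class_id: 1,  shape: ellipsoid, center: [0.30, 0.22, 0.45], radii: [0.11, 0.09, 0.11]}   # spleen-like
  - {class_id: 7,  shape: ellipsoid, center: [0.30, 0.45, 0.62], radii: [0.10, 0.11, 0.09]}   # stomach-like
  - {class_id: 2,  shape: ellipsoid, center: [0.64, 0.30, 0.40], radii: [0.08, 0.06, 0.09]}   # r-kidney-like
  - {class_id: 3,  shape: ellipsoid, center: [0.64, 0.70, 0.40], radii: [0.08, 0.06, 0.09]}   # l-kidney-like
  - {class_id: 8,  shape: tube,      center: [0.52, 0.44, 0.50], radii: [0.032, 0.032, 0.36]} # aorta-like
  - {class_id: 9,  shape: tube,      center: [0.52, 0.56, 0.50], radii: [0.030, 0.030, 0.36]} # ivc-like
  - {class_id: 10, shape: tube,      center: [0.44, 0.62, 0.58], radii: [0.022, 0.022, 0.16]} # veins-like
  - {class_id: 11, shape: blob,      center: [0.46, 0.46, 0.46], radii: [0.045, 0.11, 0.04]}  # pancreas-like
  - {class_id: 4,  shape: ellipsoid, center: [0.42, 0.58, 0.32], radii: [0.035, 0.030, 0.05]} # gallbladder-like
  - {class_id: 5,  shape: tube,      center: [0.24, 0.48, 0.50], radii: [0.026, 0.026, 0.30]} # esophagus-like
  - {class_id: 12, shape: ellipsoid, center: [0.56, 0.34, 0.52], radii: [0.028, 0.024, 0.034]} # r-adrenal-like
  - {class_id: 13, shape: ellipsoid, center: [0.56, 0.66, 0.52], radii: [0.028, 0.024, 0.034]} # l-adrenal-like
intensity_table:
  - [0.0]    # background
  - [95.0]   # spleen-like
  - [130.0]  # r-kidney-like
  - [165.0]  # l-kidney-like
  - [200.0]  # gallbladder-like
  - [235.0]  # esophagus-like
  - [270.0]  # liver-like
  - [305.0]  # stomach-like
  - [340.0]  # aorta-like
  - [375.0]  # ivc-like
  - [410.0]  # veins-like
  - [445.0]  # pancreas-like
  - [480.0]  # r-adrenal-like
  - [515.0]  # l-adrenal-like
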