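# Low signal-to-background LiDAR demo: 2 signal vs 50 background photons per
# pixel, 400 ps Gaussian pulse, first-photon SPAD over 1000 cycles.
seed: 1
scene:
  kind: lidar
  shape: [32, 32]
  depths: [0.6, 1.0, 1.5]   # inside the 1.92 m unambiguous range
  n_sig: 2.0
  n_bkg: 50.0
sim:
  nt: 128
  dt: 100.0e-12      # 128 bins x 100 ps = 12.8 ns cycle, 1.92 m range
  n_cycle: 1000
  fwhm: 400.0e-12
  detector: first_photon
recover:
  enabled: true
  coates: true
  cubelet: 8
  n_sim: 10
  s_intra: 21
  stride: 1
estimate:
  mode: depth
evaluate:
  inlier_pcts: [0.2, 0.5, 1.0]
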