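# Bi-exponential FLIM demo at reduced size: 200 signal photons per pixel,
# invariant lifetimes 3 ns / 1.5 ns, banded beta1 in {0.1, 0.5, 0.9}.
seed: 1
scene:
  kind: flim
  shape: [24, 24]
  tau1: 3.0e-9
  tau2: 1.5e-9
  beta_values: [0.1, 0.5, 0.9]
  n_sig: 200.0
  n_bkg: 0.0
sim:
  nt: 256
  dt: 50.0e-12       # 12.8 ns cycle (~78 MHz repetition)
  n_cycle: 50000
  fwhm: 200.0e-12    # delta-like vs the cycle, wide enough for a noise band
  detector: first_photon
recover:
  enabled: true
  coates: true
  cubelet: 8
  n_sim: 10
  s_intra: 21
  stride: 1
estimate:
  mode: flim-bi
  tau1: 3.0e-9
  tau2: 1.5e-9
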