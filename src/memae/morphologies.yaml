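# Stock synthetic beat morphologies (version 1).
#
# waves: name -> [amplitude, center_fraction, width_fraction]
# paced_spike: [amplitude, width_samples, center_fraction] or null
# baseline_wander: [amplitude, cycles_per_window]
version: 1
classes:
  routine:
    waves:
      P: [0.15, 0.18, 0.035]
      Q: [-0.12, 0.43, 0.012]
      R: [1.0, 0.47, 0.016]
      S: [-0.22, 0.51, 0.014]
      T: [0.35, 0.72, 0.06]
    paced_spike: null
    qrs_width_multiplier: 1.0
    noise_sd: 0.03
    baseline_wander: [0.05, 0.7]
  paced:
    waves:
      P: [0.0, 0.18, 0.035]
      Q: [-0.1, 0.43, 0.012]
      R: [0.9, 0.47, 0.016]
      S: [-0.35, 0.52, 0.014]
      T: [-0.3, 0.74, 0.065]
    paced_spike: [1.1, 1.5, 0.40]
    qrs_width_multiplier: 2.6
    noise_sd: 0.03
    baseline_wander: [0.05, 0.7]
  # identical to "paced" except for the stimulus spike: the LBBB-like confounder
  wide_qrs:
    waves:
      P: [0.0, 0.18, 0.035]
      Q: [-0.1, 0.43, 0.012]
      R: [0.9, 0.47, 0.016]
      S: [-0.35, 0.52, 0.014]
      T: [-0.3, 0.74, 0.065]
    paced_spike: null
    qrs_width_multiplier: 2.6
    noise_sd: 0.03
    baseline_wander: [0.05, 0.7]
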