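# Default acquisition protocols, quantification constants and phantom spec.
stair:
  tr_ms: 250.0
  ti_ms: 117.0
  te_ms: 5.5
  flip_deg: 90.0
  nex: 30
  label: STAIR-EPI
pd:
  tr_ms: 250.0
  ti_ms: null
  te_ms: 5.5
  flip_deg: 5.0
  nex: 10
  label: PD-EPI
constants:
  t1_mw_ms: 220.0
  t2s_mw_ms: 10.0
  t2s_total_ms: 60.0
  q_mw: -0.75
  q_long: -1.0
  t1_suppress_lo_ms: 600.0
  t1_suppress_hi_ms: 2000.0
# HS1 adiabatic full-passage pulse; peak_b1_hz was calibrated as the
# smallest 50 Hz grid value fully inverting long-T2 water (q <= -0.98).
afp_pulse:
  duration_ms: 8.64
  beta: 5.0
  mu: 4.9
  n_samples: 2048
  peak_b1_hz: 700.0
phantom:
  shape: [64, 64, 15]
  voxel_mm: [1.72, 1.72, 5.0]
  n_lesions: 0
  lesion_radius_vox: [2.0, 3.0]
  noise_sigma: 0.01
  mode: model_matched
  seed: 0
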