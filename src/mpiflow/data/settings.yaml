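# Canonical four-setting registry of the stenosis-phantom experiment.
# Flows are flow-meter ground truth (mean +/- sd, ml/min); velocities are
# the tabulated rounded reference values (cm/s).
fov_length_mm: 22.4
settings:
  - id: 1
    diameter_mm: 4.0
    flow_ml_min: 151.0
    flow_sd_ml_min: 24.5
    reference_velocity_cm_s: 20.0
    role: rest
  - id: 2
    diameter_mm: 6.0
    flow_ml_min: 680.0
    flow_sd_ml_min: 40.4
    reference_velocity_cm_s: 40.0
    role: hyperaemia_healthy
  - id: 3
    diameter_mm: 6.0
    flow_ml_min: 205.0
    flow_sd_ml_min: 26.2
    reference_velocity_cm_s: 12.0
    role: hyperaemia_stenosis
    stenosis:
      min_lumen_mm: 1.5
      length_mm: 10.0
  - id: 4
    diameter_mm: 6.0
    flow_ml_min: 410.0
    flow_sd_ml_min: 32.3
    reference_velocity_cm_s: 24.0
    role: double_hyperaemia_stenosis
    stenosis:
      min_lumen_mm: 1.5
      length_mm: 10.0
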