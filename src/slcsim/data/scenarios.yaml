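# Loop parameter settings for each simulated patient state.
# Parameter steps are applied instantaneously at the transition; fluid
# shifts (positive = reservoir -> circulation) ramp linearly over the
# stated duration.
baseline:
  heart_rate_bpm: 60
  svr_dyne_s_cm5: 1300
  pvr_dyne_s_cm5: 110
  c_lv_mmhg_s: 1040
  fluid_shift_ml: 0

exercise:
  heart_rate_bpm: 90
  svr_dyne_s_cm5: 600
  pvr_dyne_s_cm5: 40
  c_lv_mmhg_s: 1880
  fluid_shift_ml: 700
  fluid_shift_duration_s: 20

blood_loss:
  heart_rate_bpm: 65
  svr_dyne_s_cm5: 1635
  pvr_dyne_s_cm5: 210
  c_lv_mmhg_s: 1040
  fluid_shift_ml: -300
  fluid_shift_duration_s: 20

lvc_reduction:
  heart_rate_bpm: 60
  svr_dyne_s_cm5: 1300
  pvr_dyne_s_cm5: 110
  c_lv_mmhg_s: 25
  fluid_shift_ml: 0
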