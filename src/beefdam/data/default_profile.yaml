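absorption_fraction: 1.0
birth_weight: 35.45
birth_weight_sd: 3.27
cow_dmi_cv: 0.062
cow_dmi_quad_coeffs:
- 11.697
- 0.0196
- -0.0001
dmi_log_intercept: -22.889
dmi_log_slope: 5.4702
dmi_sd_bw_fraction: 0.0013
dmi_start_day: 66
gain_cv: 0.35
gain_poly_coeffs:
- 0.5584
- 0.003574
- -4.647e-06
- -5.328e-09
half_life: 108.9
half_life_sd: 40.5
late_gain: 0.32
late_gain_sd: 0.112
late_gain_start_day: 540
milk_dm_fraction: 0.13
milk_prod_cv: 0.355
milk_prod_poly_coeffs:
- 1.445
- 0.3024
- -0.003686
- 1.63e-05
- -2.57e-08
milk_transfer_factor: 0.0213
muscle_body_ratio: 0.231
muscle_body_ratio_sd: 0.09
muscle_bw_fraction: 0.361
muscle_bw_fraction_sd: 0.117
muscle_serum_ratio: 0.08
muscle_serum_ratio_sd: 0.016
soil_fraction: 0.0243
soil_fraction_sd: 0.005
update_order: intake_first
water_finisher: 40.84
water_finisher_sd: 12.87
water_lactating_cow: 56.47
water_lactating_cow_sd: 8.16
water_rate_calf: 4.0
weaning_day: 240
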