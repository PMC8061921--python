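diameter_mm,flow_ml_min,flow_sd,ref_velocity_cm_s,ref_velocity_sd,fdhm_velocity,fdhm_velocity_sd,c_factor,c_factor_sd,fdhm_abs_err,fdhm_rel_err_pct,td_velocity,td_velocity_sd,epsilon,epsilon_sd,td_abs_err,td_rel_err_pct
4,155,24.7,20.6,3.8,25.4,2.0,22.99,1.24,4.8,23.3,30.0,1.8,31.44,1.48,9.4,45.6
4,190,25.7,25.2,4.2,30.4,2.6,23.58,1.36,5.2,20.6,20.8,3.5,28.78,2.06,4.4,17.5
4,230,26.9,30.5,4.6,24.1,3.8,21.87,0.84,6.4,21.0,32.1,3.9,30.04,2.32,1.6,5.2
4,305,29.2,40.5,5.4,40.8,4.8,22.91,1.50,0.3,0.7,39.5,5.4,29.67,2.33,1.0,2.5
4,385,31.6,51.1,6.4,50.5,6.1,22.84,1.49,0.6,1.2,40.8,7.2,28.59,1.93,10.3,20.2
4,485,34.6,64.3,7.6,67.7,5.9,23.07,1.50,3.4,5.3,70.5,8.1,30.23,2.29,6.2,9.6
6,340,30.2,20.0,2.3,22.5,1.3,18.46,0.53,2.5,12.5,35.3,1.4,73.94,3.47,15.3,76.5
6,430,32.9,25.3,2.6,25.5,1.9,18.13,0.65,0.2,0.8,31.5,2.9,70.84,6.21,6.2,24.5
6,520,35.6,30.7,2.9,32.4,2.2,18.28,0.62,1.7,5.5,28.3,3.8,67.52,6.44,2.4,7.8
6,690,40.7,40.7,3.6,36.6,3.2,17.78,0.53,4.1,10.1,36.3,5.1,67.10,6.32,4.4,10.8
6,870,46.1,51.3,4.4,54.7,3.7,18.31,0.61,3.4,6.6,44.6,6.4,66.76,6.20,6.7,13.1
6,1100,53,64.8,5.3,57.8,5.1,17.76,0.51,7.0,10.8,56.3,8.1,66.74,6.19,8.5,13.1
10,962,48.9,20.4,1.3,28.4,2.9,13.07,1.39,8.0,39.2,45.2,1.7,71.02,4.19,24.8,121.6
10,1200,56,25.5,1.6,35.1,3.6,13.05,1.40,9.6,37.6,20.1,3.7,61.76,7.67,5.4,21.2
10,1450,63.5,30.8,1.8,30.1,4.8,12.40,1.52,0.7,2.3,23.5,4.4,61.36,7.48,7.3,23.7
10,1900,77,40.3,2.3,43.3,6.2,12.59,1.52,3.0,7.4,43.2,6.1,65.26,8.21,2.9,7.2
10,2420,92.6,51.4,2.8,58.9,7.8,12.73,1.50,7.5,14.6,57.8,7.6,65.76,8.14,6.4,12.5
10,3050,111.5,64.7,3.5,39.7,5.2,11.23,0.59,25.0,38.6,52.2,9.5,62.04,7.79,12.5,19.3
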