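setting,flow_ml_min,flow_sd,ref_velocity_cm_s,ref_velocity_sd,v_icf,v_icf_sd,c_loo,c_loo_sd,icf_abs_err,icf_rel_err_pct,v_cset2,v_cset2_sd,cset2_abs_err,cset2_rel_err_pct,v_cset3,v_cset3_sd,cset3_abs_err,cset3_rel_err_pct
1,151,24.5,20,2.2,19.8,2.0,25.30,0.19,0.2,1.2,,,,,,,,
1,151,24.5,20,2.2,21.5,1.8,25.84,0.08,1.5,7.7,,,,,,,,
1,151,24.5,20,2.2,19.0,2.0,25.03,0.14,1.0,5.1,,,,,,,,
1,151,24.5,20,2.2,19.8,2.0,25.32,0.19,0.2,0.8,,,,,,,,
2,680,40.4,40,3.6,42.7,2.8,21.22,0.13,2.7,6.8,,,,,,,,
2,680,40.4,40,3.6,42.3,2.9,21.18,0.14,2.3,5.7,,,,,,,,
2,680,40.4,40,3.6,34.9,3.1,20.49,0.09,5.1,12.9,,,,,,,,
2,680,40.4,40,3.6,42.3,2.9,21.18,0.14,2.3,5.7,,,,,,,,
2,680,40.4,40,3.6,42.4,2.9,21.19,0.14,2.4,6.0,,,,,,,,
2,680,40.4,40,3.6,36.8,3.1,20.69,0.13,3.2,8.0,,,,,,,,
3,205,26.2,12,1.7,12.9,1.6,17.09,0.32,0.9,7.1,15.8,1.1,3.8,31.6,,,,
3,205,26.2,12,1.7,9.0,1.5,16.00,0.25,3.0,25.2,11.8,1.1,0.2,1.9,,,,
3,205,26.2,12,1.7,12.9,1.6,17.10,0.32,0.9,7.5,15.8,1.1,3.8,32.0,,,,
3,205,26.2,12,1.7,15.2,1.4,17.51,0.29,3.2,26.6,18.2,1.0,6.2,51.8,,,,
3,205,26.2,12,1.7,16.1,1.3,17.65,0.27,4.1,34.4,19.2,0.9,7.2,59.9,,,,
3,205,26.2,12,1.7,9.1,1.5,16.04,0.26,2.9,24.2,11.9,1.1,0.1,0.9,,,,
4,410,32.3,24,2.5,22.7,1.6,13.79,0.06,1.3,5.6,34.5,1.1,10.5,43.7,27.8,1.3,3.8,15.7
4,410,32.3,24,2.5,25.2,1.6,14.28,0.11,1.2,4.8,37.0,1.0,13.0,54.1,29.8,1.3,5.8,24.0
4,410,32.3,24,2.5,24.3,1.7,14.11,0.17,0.3,1.1,36.1,1.1,12.1,50.4,29.1,1.3,5.1,21.1
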