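study_id,method,n,sbp_mean,sbp_sd,sbp_err_mean,sbp_err_sd,sbp_slope,dbp_mean,dbp_sd,dbp_err_mean,dbp_err_sd,dbp_slope
CR17,Oscillometric method with PTT,85,130.42,17.56,-0.01,7.98,0,97.7,13.15,0.01,5.39,0
CR14,Oscillometric method on wrist,85,131.4,21.35,0.89,5.65,0,84.3,15.7,-1.44,5.61,0
CR18,Oscillometric method on wrist,33,140.1,23.7,-0.7,6.9,0,87.1,16.2,-1,5.1,0
CR19,Smart phone-based finger oscillometric method,31,107,8.5,3.3,8.8,0,74.5,7.25,-5.6,7.7,0
CR20,Finapres,102,127.98,20.34,-1.83,6.83,0,78.5,12.03,0.88,7.49,0
CR21,PTT with ML algorithms,3077,123.6,21.2,2.31,9.57,0,83.4,12.1,1.33,6.43,0
CR22,PTT(PAT) using ECG and PPG,22,128.5,8.2,0.01,9.69,0,76,7.7,0.04,9.68,0
CR15,PTT(PAT) using ECG and PPG,33,121.4,17.6,-0.06,6.63,0,76.7,10.5,-0.25,5.63,0
CR23,BIM on the finger with ML algorithms,10,151,20.67,0.11,5.27,0,82,13.33,0.11,3.87,0
CR24,PPG on the finger with ML algorithms,89,127.5,15.83,0.16,5.9,0,82.5,13.17,-0.07,4.68,0
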