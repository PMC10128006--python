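culture_id,Rc,Mh,Mc,Dv,sulfate,replicate,cellulose_mg,ch4_mmol,co2_mmol,h2_mmol,h2s_mmol,acetate_mmol,lactate_mmol,glucose_umol,cellobiose_umol,se_cellulose_mg,se_ch4_mmol,se_co2_mmol,se_h2_mmol,se_h2s_mmol,se_acetate_mmol,se_lactate_mmol,se_glucose_umol,se_cellobiose_umol
mono_Rc,1,0,0,0,0,mean,184.39,0,0.98,1.36,0,0.78,0.27,0.35,2.34,0.54,0,0.01,0.02,0,0.002,0.001,0.002,0.02
bi_Rc_Mc,1,0,1,0,0,mean,197.77,0.18,1.08,1.47,0,0.48,0.29,0.19,7.30,2.23,0.003,0.03,0.03,0,0.01,0.005,0.02,1.75
bi_Rc_Mh,1,1,0,0,0,mean,198.17,0.42,0.99,1.23,0,0.78,0.29,0.23,3.71,2.60,0.007,0.03,0.01,0,0.02,0.005,0.01,0.16
bi_Rc_Dv,1,0,0,1,0,mean,203.73,0,1.04,1.52,0,0.65,0.13,1.51,9.83,0.77,0,0.03,0.003,0,0.006,0.005,0.12,0.24
bi_Rc_Dv_sulfate,1,0,0,1,1,mean,205.43,0,0.92,1.21,1.17,0.59,0.26,1.25,6.14,0.31,0,0.003,0.002,0.01,0.03,0.006,0.03,0.04
tri_Rc_Mh_Mc,1,1,1,0,0,mean,207.11,0.62,1.14,1.42,0,0.60,0.29,0.64,3.55,1.00,0.02,0.01,0.03,0,0.02,0.02,0.004,0.47
tri_Rc_Mc_Dv,1,0,1,1,0,mean,200.98,0.16,1.11,1.30,0,0.52,0.15,4.51,15.24,1.27,0.01,0.02,0.01,0,0.01,0.009,0.08,0.01
tri_Rc_Mh_Dv,1,1,0,1,0,mean,200.67,0.89,1.22,1.32,0,0.71,0.14,2.89,6.45,4.09,0.02,0.03,0.03,0,0.02,0.001,0.13,0.06
tri_Rc_Mh_Mc_sulfate,1,1,1,0,1,mean,201.46,0.53,1.15,1.27,0,0.59,0.30,0.21,4.08,0.97,0.003,0.005,0.01,0,0.01,0.004,0.01,0.09
tri_Rc_Mc_Dv_sulfate,1,0,1,1,1,mean,200.49,0.14,0.99,1.09,1.17,0.44,0.27,4.40,13.93,1.26,0.001,0.03,0.01,0.01,0.002,0.006,0.12,0.06
tri_Rc_Mh_Dv_sulfate,1,1,0,1,1,mean,197.87,0.74,0.97,1.04,1.17,0.62,0.28,2.13,3.10,0.47,0.007,0.005,0.01,0.01,0.005,0.005,0.09,0.02
quad,1,1,1,1,0,mean,210.02,1.37,1.28,1.30,0,0.55,0.13,1.66,1.70,2.10,0.03,0.007,0.02,0,0.01,0.004,0.11,0.20
quad_sulfate,1,1,1,1,1,mean,205.44,1.21,1.00,1.07,1.17,0.49,0.23,1.15,2.33,1.63,0.03,0.02,0.01,0.01,0.001,0.005,0.03,0.11
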