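sample_id,Cinnamaldehyde_mean,Cinnamaldehyde_sd,Coumarin_mean,Coumarin_sd,Methoxy cinnamaldehyde_mean,Methoxy cinnamaldehyde_sd,Cinnamic acid_mean,Cinnamic acid_sd,Benzoic acid_mean,Benzoic acid_sd,Methyl salicylate_mean,Methyl salicylate_sd,Quinic acid_mean,Quinic acid_sd,Eugenol_mean,Eugenol_sd,alpha-Glucose_mean,alpha-Glucose_sd,beta-Glucose_mean,beta-Glucose_sd,Fructose_mean,Fructose_sd,Formic acid_mean,Formic acid_sd,Choline_mean,Choline_sd,Shikimic acid_mean,Shikimic acid_sd,Succinic acid_mean,Succinic acid_sd,Alanine_mean,Alanine_sd
Cin_veru_01,9.57,0.05,0.8,0.04,10.43,0.07,3.95,0.03,0.09,0,0.7,0.01,9.16,0.04,6.44,0.04,3.07,0.11,4.74,0.02,3.94,0,0.06,0,0.55,0,1.95,0.02,3.4,0.17,1.6,0.02
Cin_veru_02,0.13,0,ND,ND,0.32,0,0.11,0,ND,ND,ND,ND,0.18,0,0.16,0,0.08,0,0.11,0,0.08,0,ND,ND,ND,ND,0.12,0,0.13,0.07,0.18,0
Cin_veru_03,1.14,0.01,0.17,0.01,0.8,0.05,0.3,0.02,ND,ND,0.12,0.01,0.58,0.03,0.7,0.04,0.21,0,0.35,0.02,0.24,0,ND,ND,ND,ND,0.25,0.01,ND,ND,0.22,0.01
Cin_cass_04,2.88,0.05,0.79,0.02,2.03,0.04,0.72,0.02,ND,ND,0.13,0,2.51,0.06,2.02,0.04,0.79,0.02,1.29,0.03,1,0,ND,ND,ND,ND,0.34,0.01,ND,ND,0.21,0.01
Cin_burm_05,1.61,0.05,0.58,0.01,1.79,0.03,0.62,0.01,ND,ND,0.12,0,2.03,0.03,1.54,0.02,0.75,0.02,1.1,0.02,0.83,0,ND,ND,0.06,0,0.35,0.01,ND,ND,0.27,0.01
Cin_cass_06,ND,ND,0.09,0.02,0.98,0.22,0.16,0.04,ND,ND,ND,ND,0.76,0.16,0.42,0.1,0.39,0.05,0.51,0.1,0.3,0.1,ND,ND,0.07,0,0.11,0.03,ND,ND,ND,ND
Cin_cass_07,ND,ND,ND,ND,1.79,0.07,0.05,0,ND,ND,0.16,0.01,0.34,0.02,0.09,0,1.93,0.21,0.15,0,0.14,0,ND,ND,0.14,0,ND,ND,ND,ND,ND,ND
Cin_veru_08,0.15,0.01,0.07,0.01,0.36,0.03,0.12,0.01,ND,ND,ND,ND,0.2,0.02,0.18,0.02,0.09,0.01,0.13,0.01,0.09,0,ND,ND,ND,ND,0.13,0.01,0.11,0.01,0.2,0.02
Cin_burm_09,0.21,0.02,0.15,0.01,0.48,0.05,0.25,0.02,ND,ND,ND,ND,0.61,0.07,0.51,0.06,0.23,0.01,0.33,0.03,0.23,0,ND,ND,0.31,0.1,0.1,0.02,0.48,0.06,0.06,0.01
Cin_veru_10,ND,ND,0.11,0,0.74,0.01,0.19,0.01,ND,ND,0.06,0,0.66,0.01,0.25,0,0.25,0.01,0.33,0.01,0.25,0,ND,ND,0.4,0,0.16,0.01,0.65,0.47,0.11,0
Cin_cass_11,ND,ND,1.13,0.02,32.64,0.38,2.59,0.04,ND,ND,1.81,0.03,27.46,0.36,3.59,0.05,11.46,0.07,14.89,0.16,10.67,0.1,ND,ND,1.84,0.1,1.46,0.02,0.09,0,0.54,0.01
Cin_cass_12,24.63,0.14,6.94,0.04,15.76,0.01,6.37,0.02,0.08,0,1.06,0.01,17.89,0.06,14.97,0.06,5.84,0.25,9.23,0.05,7.1,0,0.07,0,0.35,0,2.82,0.02,0.12,0,1.79,0.01
Cin_veru_13,1.92,0.23,0.3,0.02,16.52,0.09,4.33,0.05,0.88,0.01,1.43,0.03,6.95,0.04,3.53,0.04,2.34,0.09,3.81,0.02,3.05,0,0.09,0,0.44,0,4.7,0.05,0.35,0,6.09,0.05
Cin_veru_14,1.16,0.21,0.65,0.05,6.44,0.11,0.79,0.05,2.62,0.21,0.06,0,0.51,0.03,20.93,8.3,2.98,0.29,0.71,0.05,0.34,0.1,ND,ND,0.32,0,0.39,0.02,0.3,0.01,5.98,0.47
Cin_cass_15,23.86,0.64,2.6,0.09,10.86,0.29,3.87,0.11,ND,ND,4.55,0.11,10.23,0.35,6.7,0.19,4.33,0.38,4.86,0.19,3.55,0.1,ND,ND,0.39,0,2.76,0.09,1.03,0.11,4.06,0.12
Cin_veru_16,ND,ND,ND,ND,5.56,0.04,ND,ND,ND,ND,0.19,0,0.36,0.01,0.06,0,1.03,0.04,0.8,0.01,0.16,0,ND,ND,0.38,0,ND,ND,ND,ND,ND,ND
Cin_cass_17,ND,ND,0.15,0.01,4.73,0.36,0.35,0.03,ND,ND,0.25,0.02,3.82,0.29,0.49,0.04,1.62,0.15,2.12,0.14,1.54,0.1,ND,ND,0.16,0,0.18,0.02,0.14,0.06,0.07,0
Cin_cass_18,0.27,0.01,0.16,0,0.58,0,0.23,0,ND,ND,ND,ND,0.64,0,0.39,0,0.18,0,0.32,0,0.26,0,ND,ND,0.06,0,0.09,0,0.06,0,0.06,0
Cin_cass_19,0.3,0,0.16,0,0.56,0,0.23,0,ND,ND,ND,ND,0.6,0.01,0.45,0,0.17,0,0.3,0,0.24,0,ND,ND,0.06,0,0.1,0,0.07,0.01,0.07,0
Cin_cass_20,0.35,0,9.2,0.09,28.97,0.3,13.19,0.13,0.4,0.01,2.38,0.02,18.95,0.17,10.89,0.09,5.19,0.03,9.46,0.08,8.44,0.1,0.15,0,0.53,0,8.42,0.08,0.68,0.01,11.31,0.12
Cin_cass_21,1.97,0.03,3.72,0.01,12.04,0.03,3.76,0.02,0.13,0,0.89,0,6.6,0.02,2.68,0,2.38,0.04,3.59,0.02,2.82,0,0.13,0,0.52,0,2.14,0,0.17,0,2.59,0.01
Cin_veru_22,ND,ND,ND,ND,4.95,0.02,ND,ND,ND,ND,0.16,0,0.33,0,ND,ND,0.85,0.01,0.75,0.01,0.15,0,ND,ND,0.33,0,ND,ND,ND,ND,ND,ND
Cin_veru_23,ND,ND,ND,ND,5.04,0.05,ND,ND,ND,ND,0.16,0,0.33,0.01,0.06,0,0.91,0.04,0.77,0.01,0.15,0,ND,ND,0.33,0,0.05,0.01,0.09,0.01,ND,ND
Cin_veru_24,1.28,0.05,0.51,0.02,2.66,0.12,0.92,0.03,0.16,0.01,0.3,0.01,1.48,0.06,1.28,0.05,0.72,0.03,0.96,0.03,0.63,0,0.13,0,0.37,0,0.94,0.03,1.15,0.07,1.48,0.05
Cin_veru_25,5.23,0.12,0.5,0.11,20.81,0.88,4.96,0.15,0.14,0.01,2.63,0.07,19.13,0.78,6.79,0.16,6.78,0.18,8.91,0.36,7.5,0.3,0.3,0.01,0.95,0.1,4.4,0.12,1.44,0.05,3.23,0.1
Cin_veru_26,14.98,0.2,0.66,0.03,27.15,0.37,7.52,0.05,0.26,0,4.03,0.02,19.16,0.17,6.07,0.01,7.48,0.03,9.36,0.11,7.51,0.1,0.25,0,0.67,0,6.48,0.03,1.16,0.36,6.55,0.07
Cin_veru_27,2.99,0.12,0.97,0.07,13.58,0.42,3.72,0.12,0.77,0.02,1.54,0.05,6.1,0.19,3,0.09,1.88,0.06,3.28,0.11,2.7,0.1,0.07,0,0.43,0,4.06,0.11,0.31,0.01,5.35,0.12
Cin_veru_28,8.75,0.04,0.25,0.01,6.28,0.02,2.17,0.02,0.29,0,0.92,0.01,5.01,0.03,5.29,0.05,1.88,0.05,2.91,0.03,2.01,0,ND,ND,0.45,0,1.95,0.03,0.08,0,1.46,0.02
Cin_veru_29,0.35,0,0.58,0.05,61.79,1.21,42.99,1.15,0.4,0.01,6.39,0.17,18.65,0.4,2.59,0.06,12.1,0.4,7.75,0.14,9.34,0.2,0.28,0.01,0.78,0,5.57,0.15,0.55,0.27,1.48,0.05
Cin_burm_30,18.81,0.11,4.75,0.05,8.55,0.07,3.72,0.04,0.07,0,1.19,0,8.38,0.05,6.3,0.06,3.43,0.08,4.29,0.02,3.29,0,0.06,0,0.43,0,2.29,0.03,0.36,0.33,2.55,0.02
Cin_burm_31,21.99,0.2,5.63,0.07,11.42,0.15,4.67,0.06,0.08,0,0.83,0.01,12.3,0.15,4.7,0.12,4.42,0.08,6.47,0.06,5.01,0.1,0.07,0,0.41,0,2.12,0.03,0.43,0.14,1.73,0.02
Cin_burm_32,21.77,0.08,5.73,0.04,12.64,0.05,5.19,0.04,0.08,0,0.87,0,14.14,0.05,1.33,0.09,5.08,0.12,7.39,0.02,5.68,0,0.08,0,0.39,0,2.41,0.02,1.01,0.2,1.86,0.02
Cin_burm_33,22.57,0.15,5.87,0.03,12.34,0.18,4.89,0.03,0.08,0,0.86,0.01,13.34,0.18,1.03,0.06,4.41,0.08,6.99,0.06,5.43,0.1,0.08,0,0.41,0,2.19,0.02,0.48,0.27,1.76,0.01
Cin_burm_34,18.98,0.25,4.6,0,7.95,0.07,3.4,0.05,0.06,0,1.14,0,7.64,0.07,5.5,0.01,3.29,0.07,3.88,0.05,2.96,0,ND,ND,0.48,0,3.58,0.01,0.97,0.39,2.98,0.01
Cin_veru_35,ND,ND,ND,ND,3.17,0.09,ND,ND,ND,ND,0.12,0,0.3,0.01,ND,ND,0.67,0.01,0.53,0.02,0.13,0,ND,ND,0.36,0,0.06,0,1.56,1.32,0.06,0
Cin_veru_36,ND,ND,ND,ND,57.62,0.88,40.41,0.63,0.36,0,5.82,0.12,17.22,0.25,2.38,0.04,11.5,0.02,7.44,0.08,8.58,0.1,0.25,0,0.77,0,5.17,0.06,0.34,0.13,1.43,0.02
Cin_veru_37,13.47,1.23,1.12,0.09,3.2,0.24,1.92,0.14,0.17,0.01,0.72,0.07,3.86,0.3,6.68,0.51,1.46,0.06,2.34,0.18,1.44,0.1,ND,ND,0.29,0,2.11,0.13,0.32,0.19,1.63,0.09
Cin_veru_38,ND,ND,ND,ND,2.1,0.11,ND,ND,ND,ND,0.08,0,0.22,0,ND,ND,0.4,0.02,0.39,0.01,0.1,0,ND,ND,0.38,0,ND,ND,0.19,0.09,0.07,0.02
Cin_veru_39,0.31,0.01,0.49,0.17,65.4,0.51,36.83,0.34,0.35,0,6.21,0.05,19.86,0.14,4.69,0.06,13.86,0.24,9.34,0.06,9.63,0.1,0.24,0,0.8,0,5.49,0.06,0.78,0.06,1.41,0.01
Cin_cass_40,ND,ND,0.09,0.03,4.49,0.53,1.65,0.82,ND,ND,0.17,0.02,1.21,0.17,0.32,0.03,1.18,0.17,1.14,0.15,0.49,0.1,ND,ND,0.48,0,0.11,0.02,0.36,0.12,0.1,0.02
Cin_veru_41,ND,ND,ND,ND,2.01,0.04,ND,ND,ND,ND,0.08,0,0.21,0.01,ND,ND,0.43,0.01,0.35,0.01,0.09,0,ND,ND,0.32,0,ND,ND,0.69,0.03,0.06,0
Cin_veru_42,ND,ND,ND,ND,1.91,0.03,ND,ND,ND,ND,0.07,0,0.19,0.01,ND,ND,0.36,0,0.35,0,0.09,0,ND,ND,0.37,0,ND,ND,ND,ND,0.06,0
Cin_veru_43,ND,ND,ND,ND,1.91,0.02,ND,ND,ND,ND,0.07,0,0.19,0,ND,ND,0.36,0,0.34,0.01,0.09,0,ND,ND,0.35,0,ND,ND,ND,ND,ND,ND
Cin_veru_44,ND,ND,ND,ND,2.2,0.02,ND,ND,ND,ND,0.08,0,0.22,0,ND,ND,0.42,0,0.4,0.01,0.09,0,ND,ND,0.24,0,ND,ND,0.53,0.1,ND,ND
Cin_veru_45,9.61,0.14,0.21,0.02,6.04,0.12,2.19,0.04,0.23,0,0.9,0.02,5.7,0.08,5.37,0.07,2.05,0.05,3.14,0.04,2.22,0,ND,ND,0.41,0,2.07,0.03,0.4,0.02,1.57,0.02
Cin_veru_46,24.95,0.37,0.21,0.06,9.15,0.2,5.22,0.11,0.09,0,2.1,0.04,7.08,0.16,4.06,0.08,3.4,0.07,3.76,0.07,2.76,0.1,0.06,0,0.4,0,2.68,0.06,0.4,0.01,3.02,0.07
Cin_veru_47,ND,ND,0.38,0.09,68.01,0.6,38.28,0.57,0.36,0,6.57,0.06,21.08,0.18,5.12,0.04,13.94,0.19,9.82,0.05,10.19,0.1,0.25,0,0.83,0,5.71,0.06,0.51,0.21,1.47,0.02
Cin_veru_48,ND,ND,ND,ND,4.71,0.07,ND,ND,ND,ND,0.16,0,0.31,0.01,ND,ND,0.84,0.02,0.68,0.01,0.14,0,ND,ND,0.36,0,ND,ND,0.52,0.18,0.09,0
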