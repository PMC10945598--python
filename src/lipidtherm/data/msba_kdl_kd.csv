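condition,variant,temperature_K,kd1_uM,kd1_sd,kd2_uM,kd2_sd,kd3_uM,kd3_sd,r2,chi2
apo,WT,288,0.69,0.06,2.64,0.16,6.60,0.54,0.99,0.01
apo,WT,293,0.75,0.04,2.86,0.23,6.94,0.56,0.99,0.01
apo,WT,298,0.68,0.05,2.53,0.17,6.01,0.40,0.99,0.01
apo,WT,303,0.43,0.05,1.36,0.10,3.30,0.23,0.96,0.06
apo,R78A,288,1.91,0.17,6.18,0.80,,,0.98,0.04
apo,R78A,293,1.87,0.18,6.18,0.37,,,0.98,0.05
apo,R78A,298,2.00,0.20,5.23,0.47,,,0.98,0.04
apo,R78A,303,7.68,0.47,5.72,0.21,,,1,0
apo,R188A,288,2.21,0.17,11.01,1.95,,,0.99,0.03
apo,R188A,293,2.28,0.12,11.62,2.17,,,0.99,0.03
apo,R188A,298,1.98,0.07,8.92,0.73,,,0.99,0.03
apo,R188A,303,1.32,0.05,4.37,0.13,,,0.95,0.12
apo,R238A,288,2.48,0.12,4.74,0.45,,,0.99,0.02
apo,R238A,293,3.55,0.10,6.21,0.40,,,1,0.01
apo,R238A,298,4.70,0.07,9.66,0.82,,,1,0.01
apo,R238A,303,4.71,0.20,9.94,0.40,,,1,0.02
apo,K243A,288,1.24,0.07,7.28,0.78,,,0.99,0.03
apo,K243A,293,1.41,0.09,7.38,0.53,,,0.99,0.02
apo,K243A,298,1.28,0.05,6.65,0.50,,,0.99,0.02
apo,K243A,303,0.74,0.07,3.73,0.32,,,0.97,0.06
apo,K299A,288,2.32,0.06,6.07,0.33,17.54,6.77,1,0.01
apo,K299A,293,2.35,0.07,5.75,0.07,16.03,3.18,0.99,0.02
apo,K299A,298,2.12,0.09,5.07,0.12,14.01,1.59,0.99,0.02
apo,K299A,303,1.38,0.01,2.91,0.02,5.91,0.55,0.97,0.05
apo,R78A K299A,288,2.56,0.17,7.77,0.11,,,0.98,0.06
apo,R78A K299A,293,3.08,0.13,8.92,0.39,,,0.99,0.03
apo,R78A K299A,298,3.17,0.17,6.78,0.82,,,0.99,0.02
apo,R78A K299A,303,6.91,0.66,11.96,2.83,,,0.99,0.03
apo,R188A R238A,288,5.55,0.87,,,,,0.99,0.02
apo,R188A R238A,293,8.51,0.67,,,,,1,0.01
apo,R188A R238A,298,13.01,0.43,,,,,1,0
apo,R188A R238A,303,11.14,0.23,,,,,1,0
apo,R188A K243A,288,1.06,0.02,5.84,0.29,,,0.99,0.01
apo,R188A K243A,293,1.07,0.02,6.07,0.13,,,0.99,0.01
apo,R188A K243A,298,1.05,0.02,5.82,0.06,,,0.99,0.02
apo,R188A K243A,303,0.75,0.01,4.35,0.17,,,0.99,0.03
apo,R188A K299A,288,13.86,0.85,13.83,3.23,,,0.99,0.04
apo,R188A K299A,293,12.55,0.64,14.29,2.18,,,0.99,0.03
apo,R188A K299A,298,9.82,0.70,11.50,1.04,,,0.98,0.05
apo,R188A K299A,303,4.86,0.44,8.56,0.20,,,0.99,0.04
apo,R238A K243A,288,2.79,0.20,7.93,0.47,,,0.98,0.06
apo,R238A K243A,293,3.26,0.09,7.39,0.50,,,0.99,0.03
apo,R238A K243A,298,6.53,0.2,8.97,0.15,,,1,0
apo,R238A K243A,303,7.63,0.26,10.78,2.19,,,1,0.01
apo,R188A R238A K243A,288,20.53,2.25,,,,,1,0
apo,R188A R238A K243A,293,21.09,2.84,,,,,1,0
apo,R188A R238A K243A,298,19.80,1.71,,,,,1,0
apo,R188A R238A K243A,303,13.12,0.81,,,,,1,0
trapped,WT,293,0.51,0.04,1.16,0.07,,,0.97,0.08
trapped,WT,298,0.44,0.02,0.93,0.09,,,0.94,0.17
trapped,WT,303,0.38,0.02,0.73,0.05,,,0.94,0.15
trapped,WT,310,0.31,0.01,0.53,0.04,,,0.92,0.2
trapped,R188A,293,1.56,0.09,3.46,0.15,10.98,1.15,0.98,0.07
trapped,R188A,298,1.53,0.11,3.40,0.21,10.15,1.62,0.98,0.06
trapped,R188A,303,1.35,0.10,2.90,0.26,9.02,1.11,0.98,0.05
trapped,R188A,310,0.93,0.09,1.89,0.24,5.50,1.10,0.97,0.07
trapped,R238A,293,1.67,0.23,6.71,1.38,,,0.99,0.05
trapped,R238A,298,0.91,0.10,3.15,0.12,,,0.98,0.06
trapped,R238A,303,0.34,0.04,1.09,0.23,3.75,0.60,0.95,0.11
trapped,R238A,310,0.10,0.02,0.33,0.11,0.92,0.38,1,0
trapped,K243A,293,2.01,0.06,5.26,0.85,,,0.99,0.02
trapped,K243A,298,1.46,0.01,3.90,0.48,,,0.99,0.03
trapped,K243A,303,0.60,0.02,1.54,0.12,3.72,0.54,0.98,0.04
trapped,K243A,310,0.25,0.02,0.46,0.02,1.06,0.04,0.89,0.2
trapped,R188A R238A,293,1.24,0.10,4.82,0.16,,,0.99,0.03
trapped,R188A R238A,298,1.17,0.11,4.65,0.92,,,0.99,0.02
trapped,R188A R238A,303,0.87,0.06,3.05,0.26,,,0.98,0.04
trapped,R188A R238A,310,0.39,0.05,1.28,0.09,6.36,1.07,0.98,0.04
trapped,R188A K243A,293,3.64,0.28,15.66,4.76,,,0.99,0.03
trapped,R188A K243A,298,2.23,0.07,6.68,0.17,,,0.99,0.03
trapped,R188A K243A,303,1.06,0.05,3.10,0.33,19.33,3.70,0.99,0.03
trapped,R188A K243A,310,0.66,0.02,1.56,0.04,5.70,0.93,0.98,0.04
trapped,R238A K243A,293,1.31,0.04,4.35,0.07,,,0.99,0.03
trapped,R238A K243A,298,1.03,0.09,3.65,0.15,,,0.99,0.02
trapped,R238A K243A,303,0.48,0.05,1.97,0.09,,,0.97,0.09
trapped,R238A K243A,310,0.10,0.02,0.58,0.06,,,0.74,0.93
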