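Joint,MAE_x,RMSE_x,MAE_y,RMSE_y,MAE_z,RMSE_z
Head,6.35,9.46,2.59,3.59,7.10,9.58
Neck,5.68,8.71,2.47,3.23,6.47,8.87
Spine Shoulder,5.51,8.46,2.13,3.02,6.30,8.61
Shoulder Left,5.82,8.80,2.28,3.28,5.77,8.01
Shoulder Right,5.64,8.58,2.66,4.02,6.01,8.11
Elbow Left,6.41,9.12,3.26,5.01,7.08,9.61
Elbow Right,6.85,9.63,3.61,5.62,7.30,9.81
Wrist Left,9.23,12.66,4.02,5.71,12.45,16.23
Wrist Right,9.62,13.14,4.13,6.14,13.03,16.52
Spine Mid,5.05,7.81,2.02,2.86,5.71,7.85
Spine Base,4.55,7.12,2.45,3.87,4.87,6.72
Hip Left,4.54,7.02,2.45,3.87,4.72,6.56
Hip Right,4.45,7.02,2.56,4.04,4.82,6.67
Knee Left,4.46,7.01,3.07,4.52,2.14,3.43
Knee Right,5.10,7.42,3.27,4.72,2.50,4.21
Ankle Left,4.45,7.08,3.08,4.54,2.23,3.42
Ankle Right,5.81,8.32,3.34,5.09,1.65,4.26
Foot Left,5.48,8.25,3.72,6.02,2.05,4.12
Foot Right,6.27,8.87,3.46,5.42,2.10,4.69
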