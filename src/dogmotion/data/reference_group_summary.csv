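variable,mean_h,sd_h,mean_c,sd_c
n_distance,214.88,169.63,57.79,38.81
turn30_60,27.00,14.85,11.08,5.48
turn60_90,12.08,6.75,3.42,3.20
turn90_120,7.75,5.55,2.17,2.72
turn120,20.92,21.90,6.00,5.38
iu,25.50,19.66,9.13,4.88
number_of_points,217.42,138.43,73.33,34.92
n_average_speed,1.49,1.08,0.36,0.23
st,0.02,0.03,0.10,0.09
msd_rate,198.65,62.51,231.12,195.05
si,0.33,0.09,0.39,0.08
fd,1.40,0.11,1.20,0.10
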