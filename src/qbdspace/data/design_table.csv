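run,extraction_time,wm_ratio,extraction_number,danshensu,hydroxysafflor_yellow_A,rosmarinic_acid,lithospermic_acid,salvianolic_acid_B,dry_matter
1,1,6,3,2.114,5.822,1.610,2.229,39.76,492.3
2,0.5,10,2,1.209,5.240,2.017,2.025,40.43,466.7
3,0.5,8,3,1.387,5.135,2.206,2.267,45.67,485.8
4,1,10,3,2.340,7.707,2.172,2.630,43.60,537.3
5,1,8,2,1.934,5.786,1.980,2.247,38.38,479.9
6,1,10,1,1.089,5.016,1.565,1.601,29.44,355.8
7,2,8,1,1.674,3.605,1.418,1.628,25.56,340.1
8,1,6,1,0.601,2.588,0.979,0.932,18.76,233.3
9,0.5,8,1,0.596,2.990,1.431,1.235,28.13,318.3
10,2,8,3,3.983,5.719,2.060,2.714,39.61,586.0
11,2,10,2,3.380,4.458,2.057,2.488,35.75,491.7
12,1,8,2,1.715,6.755,2.035,2.183,37.97,437.6
13,0.5,6,2,0.926,3.071,1.858,1.679,36.21,386.0
14,1,8,2,1.834,6.565,2.077,2.304,39.62,485.2
15,2,6,2,3.151,3.614,1.821,2.091,30.58,458.3
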