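sample,assay,spike_copies_per_ul,spike_ci_low,spike_ci_high,target_copies_per_ul,target_ci_low,target_ci_high,valid_points,total_points
PL 0 (1:5),16-39,237.6,229.8,245.6,3748.5,3667.2,3831.7,18686,19678
PL 0,486-39,3438.1,3364.5,3513.4,4120.8,4020.8,4223.3,17202,19331
PL 0,660-39,2588.9,2539.8,2638.9,40.32,37.223,43.672,17564,19417
PL 0 (1:5) 1:10,16-39,24.3,21.8,27.0,387.8,376.6,399.4,15745,16444
PL 0 1:10,486-39,184.9,177.6,192.5,175.2,168.2,182.6,16184,17874
PL 0 1:10,660-39,567.6,553.93,581.54,8.56,7.2,10.2,17082,19260
PL 1 (1:5),16-39,392.2,381.6,403.2,7856,7365.6,8379,17875,19224
PL 1,486-39,2266.7,2224.4,2309.7,4295.9,4187.9,4406.6,17220,18865
PL 1,660-39,839.7,819.5,860.4,20.42,17.9,23.2,13137,16404
PL 1 (1:5) 1:10,16-39,46.1,42.8,49.8,1043.7,1022.8,1065,16922,17932
PL 1 1:10,486-39,125.7,119.9,131.8,394.12,383.1,405.4,16758,17839
PL 1 1:10,660-39,115.8,110.4,121.4,2.53,1.9,3.5,17818,19142
PL 2 (1:5),16-39,286.8,276.8,297.2,6907.2,6535.1,7300.5,13768,15156
PL 2,486-39,1141.1,1114.9,1168,567.2,551.1,583.7,12279,19292
PL 2,660-39,1305.0,1279.7,1330.8,26.78,24.2,29.6,16422,19687
PL 2 (1:5) 1:10,16-39,43.7,40.4,47.2,877.4,859,896.2,16864,19038
PL 2 1:10,486-39,188.3,181.0,195.9,112.8,107.3,118.6,16513,19004
PL 2 1:10,660-39,123.1,117.4,129.0,1.9,1.4,2.8,17112,18704
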