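sample,assay,spike_copies_per_ul,spike_ci_low,spike_ci_high,target_copies_per_ul,target_ci_low,target_ci_high,valid_points,total_points
PDX 1,16-39,430.6,418,443.5,968.4,946.9,990.4,14289,18775
PDX 1,486-39,682.8,666.8,699.1,45.2,41.8,48.9,15843,18068
PDX 1,660-39,521.2,507.9,534.9,18.8,16.7,21.2,16106,18346
PDX 1 1:10,16-39,122.4,105.8,141.7,162.29,155.7,169.2,18068,19395
PDX 1 1:10,486-39,58.0,54.3,62.1,2.93,2.2,3.9,17381,19135
PDX 1 1:10,660-39,52.7,47.5,58.4,1.72,0.9,3.0,17868,18826
PDX 2,16-39,601.9,586.6,617.7,937.7,916.8,958.9,14472,16749
PDX 2,486-39,532.9,520.1,546.1,23.8,21.5,26.4,17831,19264
PDX 2,660-39,441.6,426.6,457.2,23.2,20.2,26.5,10233,15163
PDX 2 1:10,16-39,59.7,55.9,63.8,134.7,128.8,140.9,17341,19135
PDX 2 1:10,486-39,57.5,53.2,62.2,1.5,0.9,2.4,13040,18311
PDX 2 1:10,660-39,62.3,58.3,66.4,2.8,2.1,3.8,17358,19226
PDX 3,16-39,83.5,78.9,88.4,798.1,781.0,815.5,17174,19355
PDX 3,486-39,104.7,98.6,111.2,9.9,8.2,12.0,12183,18035
PDX 3,660-39,86.1,81.5,91.1,9.0,7.6,10.7,17004,18146
PDX 3 1:10,16-39,12.9,11.2,14.8,90.5,85.6,95.5,17089,18817
PDX 3 1:10,486-39,7.3,6.7,8.7,0.5,0.3,1.0,17966,19844
PDX 3 1:10,660-39,7.7,6.4,9.2,0.5,0.3,1.1,17509,19282
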