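sample,assay,spike_copies_per_ul,spike_ci_low,spike_ci_high,target_copies_per_ul,target_ci_low,target_ci_high,valid_points,total_points
H1299,16-39,981.8,962.5,1001.5,5025.6,4880.6,5175,18079,18671
H1299,486-39,940.9,921.7,960.6,17.1,15.1,19.4,17084,19738
H1299,660-39,1275.7,1252,1299.8,112.7,107.5,118.2,18148,19385
H1299 1:10,16-39,302.9,293.4,312.8,439.3,427.4,451.5,16281,18954
H1299 1:10,486-39,345.8,335.8,356.1,1.8,1.2,2.6,17328,18723
H1299 1:10,660-39,334.3,324.4,344.5,9.2,7.7,10.9,16976,18096
A549,16-39,808.9,790.1,828.3,2130.9,2087.6,2175.1,14270,19057
A549,486-39,1309.6,1285.3,1334.3,19.9,17.8,22.3,18008,19310
A549,660-39,1403.2,1372.5,1434.6,69,64.0,74.0,12610,17988
A549 1:10,16-39,486.6,473.6,499.9,483.4,470.5,496.7,15486,16723
A549 1:10,486-39,401.3,379.9,423.8,1.57,0.7,3.5,17285,18655
A549 1:10,660-39,367.4,355.9,379.5,5.36,4.1,6.8,13841,17322
LT73,16-39,655.2,640.7,670.1,3266.7,3200.2,3334.5,18070,19251
LT73,486-39,921.1,902.2,940.4,16.5,14.6,18.8,17170,18120
LT73,660-39,574.0,558.7,589.8,4.0,3.0,5.3,13606,19582
LT73 1:10,16-39,90.4,85.5,95.5,409.9,398.6,421.5,16673,18990
LT73 1:10,486-39,66.8,62.7,71.1,1.3,0.9,2.1,17359,18326
LT73 1:10,660-39,60.8,57.0,64.8,0.3,0.1,0.8,18164,19404
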