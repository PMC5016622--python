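layer,leaf_area_cm2,petiole_cm,droop_deg,n_leaves,stem_radius_mm,internode_cm
1,181.4,7.0,30.33,4,4.3,8.3
3,189.9,6.3,37.08,4,4.5,7.5
5,200.3,5.3,34.92,4,4.1,9.2
7,220.0,6.1,29.25,4,4.2,8.8
9,200.2,5.0,45.72,4,4.0,7.9
11,269.8,5.4,36.18,4,4.4,9.0
13,243.8,5.1,57.78,4,4.4,8.5
15,181.1,3.8,51.84,6,4.2,3.4
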